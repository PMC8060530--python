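"""Pre-lockdown vs lockdown contrasts of profile prevalence.

For each profile, rows are cross-classified into a 2x2 table (period x
in-profile) and tested with the Yates continuity-corrected chi-square on 1
degree of freedom. Prevalence shifts are reported as signed percent changes
relative to the pre-lockdown prevalence, and rare profiles pooled below the
reporting floor get an exact (Clopper-Pearson) binomial confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

PERIODS = ("pre_lockdown", "lockdown")


class DegenerateTableError(ValueError):
    """A 2x2 margin is zero: the chi-square test is undefined."""


@dataclass
class PeriodContrast:
    """One profile's period contrast: counts, test, prevalences, change."""

    profile_id: int
    table: np.ndarray               # rows pre/lockdown, cols in/out
    prevalence_pre: float           # percent
    prevalence_lockdown: float      # percent
    chi2: float
    p_value: float
    pct_change: float


def contingency_table(labels: np.ndarray, period_labels: np.ndarray,
                      profile_id: int) -> np.ndarray:
    """2x2 counts (pre/lockdown x in-profile/not) for one profile."""
    labels = np.asarray(labels)
    period_labels = np.asarray(period_labels)
    if profile_id not in labels:
        raise ValueError(f"unknown profile {profile_id}")
    table = np.empty((2, 2), dtype=int)
    for r, period in enumerate(PERIODS):
        rows = period_labels == period
        if not rows.any():
            raise DegenerateTableError(f"degenerate margin: no rows in period {period!r}")
        inp = int(np.sum(rows & (labels == profile_id)))
        table[r] = (inp, int(rows.sum()) - inp)
    return table


def pearson_chi_square(table: np.ndarray) -> float:
    """Uncorrected Pearson chi-square for a 2x2 table (reference for tests)."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise DegenerateTableError("zero margin in 2x2 table")
    return float(n * (a * d - b * c) ** 2 / denom)


def yates_chi_square(table: np.ndarray) -> tuple[float, float]:
    """Continuity-corrected chi-square and two-sided p for a 2x2 table.

    chi2 = n (|ad - bc| - n/2)^2 / [(a+b)(c+d)(a+c)(b+d)], with the
    correction floored at zero so the statistic is never negative; p is the
    upper tail of chi-square with 1 df.
    """
    (a, b), (c, d) = np.asarray(table, dtype=float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise DegenerateTableError("zero margin in 2x2 table")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    chi2 = float(n * num**2 / denom)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def percent_change(p_pre: float, p_lockdown: float) -> float:
    """Signed percent change of a prevalence between periods, relative to pre."""
    if p_pre == 0:
        raise ValueError("percent change undefined for zero pre-lockdown prevalence")
    return float(100.0 * (p_lockdown - p_pre) / p_pre)


def format_percent_change(p_pre: float, p_lockdown: float) -> str:
    chg = percent_change(p_pre, p_lockdown)
    word = "increase" if chg > 0 else ("decrease" if chg < 0 else "no change")
    if chg == 0:
        return "0.0% (no change)"
    return f"{abs(chg):.1f}% {word}"


def clopper_pearson_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI for x/n via beta-quantile inversion; in percent.

    Lower bound is 0 when x = 0 and upper is 100 when x = n.
    """
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    lo = 0.0 if x == 0 else float(stats.beta.ppf(tail, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - tail, x + 1, n - x))
    return 100.0 * lo, 100.0 * hi


def reconstruct_count(pct: float, total: int) -> int:
    """Integer count from a printed prevalence: round half away from zero."""
    return int(math.floor(pct * total / 100.0 + 0.5))


def format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


# ---------------------------------------------------------------------------
# report

def build_report(labels: np.ndarray, period_labels: np.ndarray,
                 top: int = 4) -> tuple[list[PeriodContrast], pd.DataFrame, str]:
    """Per-profile contrasts for the ``top`` most prevalent profiles plus a
    pooled rare row with an exact CI.

    Returns (contrasts, table, text summary). Requires both periods present.
    """
    labels = np.asarray(labels)
    period_labels = np.asarray(period_labels)
    present = set(np.unique(period_labels))
    if not set(PERIODS) <= present:
        raise DegenerateTableError(f"need both periods, found {sorted(present)}")
    n_pre = int(np.sum(period_labels == PERIODS[0]))
    n_lock = int(np.sum(period_labels == PERIODS[1]))

    order = pd.Series(labels).value_counts().index.to_list()  # overall prevalence order
    head = sorted(order[:top])
    contrasts: list[PeriodContrast] = []
    rows = []
    lines = [f"Period contrast: {n_pre} pre-lockdown vs {n_lock} lockdown rows"]
    for pid in head:
        tab = contingency_table(labels, period_labels, pid)
        prev_pre = 100.0 * tab[0, 0] / n_pre
        prev_lock = 100.0 * tab[1, 0] / n_lock
        chi2, p = yates_chi_square(tab)
        chg = percent_change(prev_pre, prev_lock) if prev_pre > 0 else np.nan
        contrasts.append(PeriodContrast(pid, tab, prev_pre, prev_lock, chi2, p, chg))
        rows.append((f"P{pid}", tab[0, 0], tab[1, 0], round(prev_pre, 1),
                     round(prev_lock, 1), round(chi2, 2), format_p(p),
                     round(chg, 1) if np.isfinite(chg) else ""))
        chg_txt = (format_percent_change(prev_pre, prev_lock)
                   if prev_pre > 0 else "change undefined: absent pre-lockdown")
        lines.append(
            f"  Profile {pid}: {prev_pre:.1f}% -> {prev_lock:.1f}% "
            f"({chg_txt}), chi2 = {chi2:.2f}, P = {format_p(p)}"
        )

    rare = ~np.isin(labels, head)
    x_pre = int(np.sum(rare & (period_labels == PERIODS[0])))
    x_lock = int(np.sum(rare & (period_labels == PERIODS[1])))
    lo, hi = clopper_pearson_ci(x_pre, n_pre)
    rows.append(("rare_pooled", x_pre, x_lock, round(100.0 * x_pre / n_pre, 1),
                 round(100.0 * x_lock / n_lock, 1), "", "", ""))
    lines.append(
        f"  Rare profiles pooled: {100.0 * x_pre / n_pre:.1f}% of pre-lockdown rows "
        f"(95% CI {lo:.1f}-{hi:.1f}%), {x_lock} lockdown rows"
    )

    table = pd.DataFrame(rows, columns=["profile", "n_pre", "n_lock", "prev_pre_pct",
                                        "prev_lock_pct", "chi2", "p_value", "pct_change"])
    return contrasts, table, "\n".join(lines)


def save_report(table: pd.DataFrame, text: str, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "period_contrasts.csv", index=False)
    (out / "period_contrasts.txt").write_text(text + "\n")
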