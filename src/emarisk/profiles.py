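"""Risk profiles: feature-activation patterns, prevalences, signatures, coverage.

A *profile* is a distinct feature-activation pattern — a row of the fitted
binary matrix Z treated as a mutually exclusive class label. With K active
features there are at most 2^K possible profiles, the all-zero (baseline)
pattern included. Profile ids are 1..P in order of descending overall
prevalence; a profile's *signature* is the empirical probability, among its
rows, that each questionnaire item scores positive (standardized score >= the
binarization threshold), computed on observed entries only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ibp import FeatureModelState, canonicalize

logger = logging.getLogger(__name__)


@dataclass
class ProfileAssignment:
    """Per-row profile labels plus per-profile patterns, prevalence, signatures."""

    labels: np.ndarray                      # (N,) profile ids, 1..P
    patterns: dict[int, tuple[int, ...]]    # profile id -> activation pattern
    prevalence: dict[int, float]            # profile id -> fraction of rows
    signatures: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_profiles(self) -> int:
        return len(self.patterns)

    @property
    def n_rows(self) -> int:
        return len(self.labels)


def assign_profiles(map_state: FeatureModelState, rule: str = "pattern") -> ProfileAssignment:
    """Label every row with its profile.

    ``rule='pattern'`` (default): profile = the row's full activation pattern.
    ``rule='dominant_feature'``: profile = the single most widely owned active
    feature (baseline when none active) — a coarser alternative labelling.
    Ids are assigned by descending prevalence, ties broken by
    pattern-as-integer ascending.
    """
    Z = np.asarray(map_state.Z)
    if Z.shape[0] == 0:
        raise ValueError("empty model state: no rows to label")
    Zc, _, _ = canonicalize(Z)
    N, K = Zc.shape

    if rule == "pattern":
        keys = [tuple(int(z) for z in row) for row in Zc]
    elif rule == "dominant_feature":
        counts = Zc.sum(axis=0)
        keys = []
        for row in Zc:
            active = np.flatnonzero(row)
            if active.size == 0:
                keys.append(tuple(0 for _ in range(K)))
            else:
                dom = active[np.argmax(counts[active])]
                key = [0] * K
                key[dom] = 1
                keys.append(tuple(key))
    else:
        raise ValueError(f"unknown assignment rule {rule!r}")

    uniq: dict[tuple[int, ...], int] = {}
    for key in keys:
        uniq[key] = uniq.get(key, 0) + 1

    def pattern_as_int(p: tuple[int, ...]) -> int:
        return int("".join(map(str, p)) or "0", 2)

    ordered = sorted(uniq, key=lambda p: (-uniq[p], pattern_as_int(p)))
    id_of = {p: i + 1 for i, p in enumerate(ordered)}
    labels = np.array([id_of[k] for k in keys])
    patterns = {i + 1: p for i, p in enumerate(ordered)}
    prevalence = {id_of[p]: uniq[p] / N for p in ordered}
    return ProfileAssignment(labels, patterns, prevalence)


def feature_signature(assignment: ProfileAssignment, positives: np.ndarray,
                      mask: np.ndarray) -> dict[int, np.ndarray]:
    """Per-profile positive-score probability for each item.

    ``positives`` is the binarized observation matrix and ``mask`` its
    observed-entry mask. Cells with no observations for a profile are NaN
    (reported missing, never zero). Profiles with zero rows are excluded with
    a warning. The result is also stored on ``assignment.signatures``.
    """
    positives = np.asarray(positives, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    sigs: dict[int, np.ndarray] = {}
    for pid in assignment.patterns:
        rows = assignment.labels == pid
        if not rows.any():
            warnings.warn(f"profile {pid} has zero rows; excluded from signatures")
            continue
        n_obs = mask[rows].sum(axis=0).astype(float)
        n_pos = (positives[rows] & mask[rows]).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            sig = np.where(n_obs > 0, n_pos / np.maximum(n_obs, 1), np.nan)
        sigs[pid] = sig
    assignment.signatures = sigs
    return sigs


def coverage(assignment: ProfileAssignment, top_m: int) -> float:
    """Total prevalence of the top_m most prevalent profiles."""
    if not 1 <= top_m <= assignment.n_profiles:
        raise ValueError(f"top_m must be in 1..{assignment.n_profiles}, got {top_m}")
    return float(sum(assignment.prevalence[p] for p in range(1, top_m + 1)))


# ---------------------------------------------------------------------------
# serialisation

def save_assignment(assignment: ProfileAssignment, out_dir: str | Path,
                    question_ids: list[str] | None = None) -> None:
    """Write assignment, prevalence and signature tables as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"row_id": np.arange(assignment.n_rows),
                  "profile": assignment.labels}).to_csv(out / "assignment.csv", index=False)
    pd.DataFrame(
        {"profile": list(assignment.prevalence),
         "prevalence": [assignment.prevalence[p] for p in assignment.prevalence],
         "pattern": ["".join(map(str, assignment.patterns[p])) for p in assignment.prevalence]}
    ).to_csv(out / "prevalence.csv", index=False)
    if assignment.signatures:
        cols = question_ids or [f"q{j:02d}" for j in range(next(iter(assignment.signatures.values())).size)]
        sig = pd.DataFrame.from_dict(assignment.signatures, orient="index", columns=cols)
        sig.index.name = "profile"
        sig.to_csv(out / "signatures.csv", float_format="%.4f")


def plot_signatures(assignment: ProfileAssignment, question_ids: list[str],
                    path: str | Path) -> None:
    """Bar-chart panel of per-profile positive-score probabilities."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sigs = assignment.signatures
    if not sigs:
        raise ValueError("compute feature_signature before plotting")
    pids = sorted(sigs)
    fig, axes = plt.subplots(1, len(pids), figsize=(3.2 * len(pids), 8), sharey=True)
    axes = np.atleast_1d(axes)
    y = np.arange(len(question_ids))
    for ax, pid in zip(axes, pids):
        ax.barh(y, np.nan_to_num(sigs[pid]), height=0.8)
        ax.set_title(f"Profile {pid}\n({assignment.prevalence[pid]:.1%})")
        ax.set_xlim(0, 1)
        ax.set_xlabel("P(score positive)")
    axes[0].set_yticks(y)
    axes[0].set_yticklabels(question_ids, fontsize=6)
    axes[0].invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
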