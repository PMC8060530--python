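"""Synthetic EMA stream generator with latent risk profiles.

The generator emulates the study design the analysis assumes: a cohort of 36
high-suicide-risk out-patients answering 2-4 randomly chosen questionnaire
items per day at random times between 10.00 and 22.00 h, over a pre-lockdown
window (2019-10-01..2020-03-13) and a lockdown window (2020-03-14..2020-04-14).

Each patient-day carries a latent risk profile drawn i.i.d. from a
period-specific mixture; item answers are profile-conditional continuous
scores (truncated Gaussian around per-item severity means) mapped back to the
raw item scale. Uniform compliance thinning reduces the generated patient-days
to the study's observed row counts (960 pre-lockdown, 214 lockdown). Ground
truth labels are returned alongside so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .schema import (
    EMARecord,
    PeriodSchedule,
    PROMPT_WINDOW,
    POSITIVE_THRESHOLD,
    QuestionnaireSchema,
    default_schema,
    destandardize_score,
)


class ConfigError(ValueError):
    """Raised for inconsistent generator configuration."""


#: sd of the truncated-Gaussian observation noise on the standardized scale
DEFAULT_NOISE_SD = 0.15


@dataclass(frozen=True)
class ProfileTemplate:
    """A latent risk profile: per-item positive probabilities and score means.

    ``positive_prob[d]`` is the chance a standardized answer to item d scores
    positive (>= 0.5) under this profile; ``severity_means[d]`` is the latent
    Gaussian mean that realises that probability under the configured noise sd.
    """

    profile_id: int
    positive_prob: np.ndarray
    severity_means: np.ndarray

    def __post_init__(self) -> None:
        for name in ("positive_prob", "severity_means"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (32,):
                raise ConfigError(f"{name} must have length 32, got {v.shape}")
        if np.any((self.positive_prob < 0) | (self.positive_prob > 1)):
            raise ConfigError("positive_prob entries must lie in [0, 1]")


def severity_mean_for(positive_prob, noise_sd: float = DEFAULT_NOISE_SD,
                      threshold: float = POSITIVE_THRESHOLD) -> np.ndarray:
    """Gaussian mean m with P(N(m, sd) >= threshold) = positive_prob.

    Clipping the drawn score to [0, 1] does not change the positive event
    (the threshold is interior), so binarized positives track positive_prob
    exactly in expectation.
    """
    p = np.clip(np.asarray(positive_prob, dtype=float), 1e-6, 1 - 1e-6)
    return threshold + noise_sd * stats.norm.ppf(p)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort and design parameters; defaults reproduce the study conditions."""

    n_patients: int = 36
    pct_female: float = 86.1
    age_mean: float = 41.7
    age_sd: float = 16.3
    prior_attempts_mean: float = 1.1
    mixture_pre: tuple[float, ...] = (0.430, 0.178, 0.267, 0.118, 0.007)
    mixture_lockdown: tuple[float, ...] = (0.528, 0.103, 0.346, 0.023, 0.0)
    target_rows_pre: int = 960
    target_rows_lockdown: int = 214
    questions_per_day_min: int = 2
    questions_per_day_max: int = 4
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.questions_per_day_min > self.questions_per_day_max:
            raise ConfigError("questions_per_day_min must be <= max")
        for name in ("mixture_pre", "mixture_lockdown"):
            w = np.asarray(getattr(self, name))
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be non-negative and sum to 1")


def default_mixtures() -> tuple[np.ndarray, np.ndarray]:
    """Period profile mixtures (P1..P4 plus pooled rare remainder).

    Pre-lockdown prevalences 43.0/17.8/26.7/11.8% with a 0.7% rare remainder;
    lockdown 52.8/10.3/34.6/2.3% with no rare mass.
    """
    c = CohortConfig()
    return np.asarray(c.mixture_pre), np.asarray(c.mixture_lockdown)


def default_profile_templates(schema: QuestionnaireSchema | None = None,
                              noise_sd: float = DEFAULT_NOISE_SD) -> list[ProfileTemplate]:
    """The four dominant risk profiles.

    Qualitative structure: Profile 1 is low on all 32 items; Profiles 2 and 4
    are high on wish-to-die, appetite and sleep items, with Profile 4 (but not
    Profile 2) also high on negative feelings; Profile 3 is high on negative
    feelings but markedly lower than Profile 2 on the somatic/wish items.

    Profiles are *featural*: each severity-mean vector is a baseline plus
    additive symptom-feature increments on the latent score scale — a somatic
    elevation (wish/sleep/appetite, shared by Profiles 2 and 4) and a
    negative-feelings elevation (shared by Profiles 3 and 4). This mirrors the
    study's description of profiles as combinations of co-occurring symptom
    groupings. Positive probabilities follow from the means under the
    Gaussian noise. Within each domain, items alternate between two levels so
    no template is item-wise constant (real instruments are not endorsed
    uniformly). The numeric levels are package choices satisfying the
    qualitative ordering.
    """
    schema = schema or default_schema()
    somatic = np.concatenate([schema.domain_columns(d)
                              for d in ("wish_to_die_live", "sleep", "appetite")])
    neg = schema.domain_columns("negative_feelings")

    def alternating(cols: np.ndarray, lo: float, hi: float, out: np.ndarray) -> None:
        out[cols] = np.where(np.arange(cols.size) % 2 == 0, lo, hi)

    baseline = np.empty(32)
    alternating(np.arange(32), 0.30, 0.34, baseline)
    somatic_inc = np.zeros(32)
    alternating(somatic, 0.26, 0.30, somatic_inc)
    somatic_inc[neg] = 0.07           # somatic profiles carry mild dysphoria
    negative_inc = np.zeros(32)
    alternating(neg, 0.24, 0.28, negative_inc)
    negative_inc[somatic] = 0.05      # and vice versa

    def build(pid: int, means: np.ndarray) -> ProfileTemplate:
        p = stats.norm.sf(POSITIVE_THRESHOLD, loc=means, scale=noise_sd)
        return ProfileTemplate(pid, p, means)

    return [
        build(1, baseline),
        build(2, baseline + somatic_inc),
        build(3, baseline + negative_inc),
        build(4, baseline + somatic_inc + negative_inc),
    ]


def rare_profile_templates(schema: QuestionnaireSchema | None = None,
                           n: int = 4,
                           noise_sd: float = DEFAULT_NOISE_SD) -> list[ProfileTemplate]:
    """Low-distinctiveness remainder profiles (ids 5..4+n) sharing the rare mass."""
    schema = schema or default_schema()
    rng = np.random.default_rng(2021)  # fixed: templates are constants, not draws
    out = []
    for k in range(n):
        p = np.clip(0.35 + 0.15 * rng.standard_normal(32), 0.05, 0.95)
        out.append(ProfileTemplate(5 + k, p, severity_mean_for(p, noise_sd)))
    return out


def _prompt_times(day, n, rng) -> list[datetime]:
    """n distinct prompt minutes uniform in the daily window, sorted."""
    start = datetime.combine(day, PROMPT_WINDOW[0])
    span = int((datetime.combine(day, PROMPT_WINDOW[1]) - start).total_seconds() // 60)
    minutes = rng.choice(span + 1, size=n, replace=False)
    return [start + timedelta(minutes=int(m)) for m in sorted(minutes)]


def simulate_ema_stream(
    cohort: CohortConfig | None = None,
    templates: list[ProfileTemplate] | None = None,
    schema: QuestionnaireSchema | None = None,
    schedule: PeriodSchedule | None = None,
    seed: int | None = None,
) -> tuple[list[EMARecord], pd.DataFrame]:
    """Generate an EMA record stream plus its ground-truth label table.

    Returns ``(records, truth)`` where ``truth`` has one row per retained
    patient-day: row_id, patient_id, date, period, true_profile.
    """
    cohort = cohort or CohortConfig()
    schema = schema or default_schema()
    schedule = schedule or PeriodSchedule()
    if templates is None:
        templates = default_profile_templates(schema, cohort.noise_sd)
    mix_pre = np.asarray(cohort.mixture_pre)
    mix_lock = np.asarray(cohort.mixture_lockdown)
    n_named = len(templates)
    # trailing mixture entry (if any) is remainder mass spread over rare templates
    rare: list[ProfileTemplate] = []
    if len(mix_pre) == n_named + 1:
        rare = rare_profile_templates(schema, noise_sd=cohort.noise_sd)
    elif len(mix_pre) != n_named:
        raise ConfigError(
            f"mixture length {len(mix_pre)} incompatible with {n_named} templates"
        )
    if len(mix_pre) != len(mix_lock):
        raise ConfigError("period mixtures must have equal length")
    by_id = {t.profile_id: t for t in list(templates) + rare}

    if seed is None:
        seed = cohort.seed
    master = np.random.SeedSequence(seed)
    select_rng = np.random.default_rng(master.spawn(1)[0])
    # one stream per patient, keyed by (seed, patient index)
    patient_rng = {
        i: np.random.default_rng(np.random.SeedSequence([seed, i]))
        for i in range(cohort.n_patients)
    }
    patient_ids = [f"P{i + 1:03d}" for i in range(cohort.n_patients)]

    records: list[EMARecord] = []
    truth_rows = []
    row_id = 0
    for period, mix, target in (
        ("pre_lockdown", mix_pre, cohort.target_rows_pre),
        ("lockdown", mix_lock, cohort.target_rows_lockdown),
    ):
        days = schedule.days(period)
        all_cells = [(i, d) for i in range(cohort.n_patients) for d in days]
        if target > len(all_cells):
            raise ConfigError(f"target rows {target} exceed available patient-days")
        keep = select_rng.choice(len(all_cells), size=target, replace=False)
        for cell in sorted(keep):
            i, day = all_cells[cell]
            rng = patient_rng[i]
            # rare remainder mass split equally over the rare templates
            probs, ids = list(mix[:n_named]), [t.profile_id for t in templates]
            if rare and len(mix) == n_named + 1:
                probs += [mix[n_named] / len(rare)] * len(rare)
                ids += [t.profile_id for t in rare]
            pid_profile = int(rng.choice(ids, p=np.asarray(probs) / np.sum(probs)))
            tmpl = by_id[pid_profile]
            nq = int(rng.integers(cohort.questions_per_day_min, cohort.questions_per_day_max + 1))
            qcols = rng.choice(len(schema), size=nq, replace=False)
            times = _prompt_times(day, nq, rng)
            for ts, j in zip(times, qcols):
                spec = schema.questions[j]
                score = tmpl.severity_means[j] + cohort.noise_sd * rng.standard_normal()
                score = float(np.clip(score, 0.0, 1.0))
                records.append(EMARecord(patient_ids[i], ts, spec.question_id, destandardize_score(score, spec)))
            truth_rows.append((row_id, patient_ids[i], day, period, pid_profile))
            row_id += 1

    truth = pd.DataFrame(truth_rows, columns=["row_id", "patient_id", "date", "period", "true_profile"])
    return records, truth


def generate_demographics(cohort: CohortConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Synthetic patient table: age (truncated normal, >=18), sex, prior attempts."""
    cohort = cohort or CohortConfig()
    if cohort.n_patients < 1:
        raise ConfigError("n_patients must be >= 1")
    rng = np.random.default_rng(cohort.seed if seed is None else seed)
    n = cohort.n_patients
    a, b = (18 - cohort.age_mean) / cohort.age_sd, np.inf
    ages = stats.truncnorm.rvs(a, b, loc=cohort.age_mean, scale=cohort.age_sd,
                               size=n, random_state=rng)
    female = rng.random(n) < cohort.pct_female / 100.0
    attempts = rng.poisson(cohort.prior_attempts_mean, size=n)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "age": np.round(ages, 1),
            "sex": np.where(female, "F", "M"),
            "prior_attempts": attempts,
        }
    )


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)
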