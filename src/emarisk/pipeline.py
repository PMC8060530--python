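"""End-to-end orchestration: simulate -> fit -> profile -> compare.

The three stage commands (`cmd_simulate`, `cmd_fit`, `cmd_compare`) mirror the
files-on-disk workflow driven by the ``analysis/`` scripts and each write a
YAML manifest (seed, row counts, input hashes, package version).
``run_full_pipeline`` performs the same chain in memory and is what the tests
and the acceptance script call. ``published_check`` recomputes the printed worked
examples (chi-square quadruple, percent changes, exact CI) from the published
period totals and prevalences alone — no data required.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment

from . import __version__ as _pkg_version
from . import contrasts as ct
from . import ibp, profiles, simulate
from .schema import (
    ObservationMatrix,
    PeriodSchedule,
    QuestionnaireSchema,
    build_observation_matrix,
    default_schema,
    read_ema_table,
    write_ema_table,
)

logger = logging.getLogger(__name__)

#: sampler size used for study-scale runs (N ~ 1174, D = 32); the library
#: default (2000 sweeps) remains available for longer runs
STUDY_SCALE_GIBBS = ibp.GibbsConfig(n_iterations=600, burn_in=300, thin=5,
                                    init_features=6)


@dataclass
class RunConfig:
    """Paths and settings for a file-based pipeline run."""

    out_dir: Path
    schema_path: Path | None = None
    seed: int = 0
    cohort: simulate.CohortConfig | None = None
    gibbs: ibp.GibbsConfig | None = None
    schedule: PeriodSchedule | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, **fields) -> None:
    fields["package_version"] = _pkg_version
    (out / "manifest.yaml").write_text(yaml.safe_dump(fields, sort_keys=False))


def _load_schema(config: RunConfig) -> QuestionnaireSchema:
    if config.schema_path is not None:
        from .schema import load_schema

        if not Path(config.schema_path).exists():
            raise FileNotFoundError(f"schema config not found: {config.schema_path}")
        return load_schema(config.schema_path)
    return default_schema()


# ---------------------------------------------------------------------------
# stage commands

def cmd_simulate(config: RunConfig) -> tuple[Path, Path]:
    """Generate the synthetic EMA stream; write ema.csv + truth.csv + manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = _load_schema(config)
    cohort = config.cohort or simulate.CohortConfig(seed=config.seed)
    records, truth = simulate.simulate_ema_stream(
        cohort, schema=schema, schedule=config.schedule, seed=config.seed
    )
    ema_path, truth_path = out / "ema.csv", out / "truth.csv"
    write_ema_table(records, ema_path)
    simulate.write_truth_table(truth, truth_path)
    demo = simulate.generate_demographics(cohort, seed=config.seed)
    demo.to_csv(out / "demographics.csv", index=False)
    _write_manifest(
        out,
        stage="simulate",
        seed=config.seed,
        n_records=len(records),
        n_rows_pre=int((truth["period"] == "pre_lockdown").sum()),
        n_rows_lockdown=int((truth["period"] == "lockdown").sum()),
        ema_sha256=_sha256(ema_path),
    )
    logger.info("simulated %d records over %d patient-days", len(records), len(truth))
    return ema_path, truth_path


def cmd_fit(config: RunConfig, ema_csv: str | Path) -> Path:
    """Fit the latent-feature model to an EMA table; serialise the posterior."""
    schema = _load_schema(config)
    records = read_ema_table(ema_csv, schema)
    if len(records) < 2:
        raise ValueError(f"{ema_csv}: need at least 2 records to fit")
    obs = build_observation_matrix(records, schema, config.schedule)
    gibbs = config.gibbs or replace(STUDY_SCALE_GIBBS, seed=config.seed)
    summary = ibp.run_gibbs(obs.values, obs.mask, gibbs)
    out = Path(config.out_dir) / "posterior"
    ibp.save_posterior(summary, out, gibbs)
    obs.row_meta.to_csv(out / "row_meta.csv", index=False)
    _write_manifest(
        out,
        stage="fit",
        seed=gibbs.seed,
        n_rows=obs.n_rows,
        K=summary.map_state.K,
        map_logp=float(summary.map_logp),
        ema_sha256=_sha256(Path(ema_csv)),
    )
    logger.info("fit finished: K=%d, map logp=%.1f", summary.map_state.K, summary.map_logp)
    return out


def cmd_compare(config: RunConfig, posterior_dir: str | Path, ema_csv: str | Path) -> Path:
    """Profile the fitted state and contrast periods; write report files."""
    post = Path(posterior_dir)
    state = ibp.load_posterior_map(post)
    meta_path = post / "row_meta.csv"
    if not meta_path.exists():
        raise IOError(f"missing fit outputs: {meta_path}")
    row_meta = pd.read_csv(meta_path)
    schema = _load_schema(config)
    records = read_ema_table(ema_csv, schema)
    obs = build_observation_matrix(records, schema, config.schedule)
    if obs.n_rows != len(row_meta) or obs.n_rows != state.N:
        raise IOError("posterior/row_meta/EMA table are inconsistent")

    assignment = profiles.assign_profiles(state)
    profiles.feature_signature(assignment, obs.binarized(), obs.mask)
    out = Path(config.out_dir) / "report"
    profiles.save_assignment(assignment, out, obs.question_ids)
    _, table, text = ct.build_report(assignment.labels, obs.period_labels())
    ct.save_report(table, text, out)
    _write_manifest(out, stage="compare", n_profiles=assignment.n_profiles,
                    ema_sha256=_sha256(Path(ema_csv)))
    return out


# ---------------------------------------------------------------------------
# in-memory pipeline

def run_full_pipeline(
    seed: int,
    gibbs: ibp.GibbsConfig | None = None,
    cohort: simulate.CohortConfig | None = None,
) -> dict:
    """simulate -> matrix -> fit -> profiles -> contrasts, all in memory.

    Returns a dict with the observation matrix, ground truth, posterior
    summary, profile assignment (with signatures), generating templates and
    the period-contrast outputs.
    """
    schema = default_schema()
    schedule = PeriodSchedule()
    cohort = cohort or simulate.CohortConfig(seed=seed)
    templates = simulate.default_profile_templates(schema, cohort.noise_sd)
    records, truth = simulate.simulate_ema_stream(cohort, templates, schema, schedule, seed=seed)
    obs = build_observation_matrix(records, schema, schedule)

    gibbs = gibbs or replace(STUDY_SCALE_GIBBS, seed=seed)
    summary = ibp.run_gibbs(obs.values, obs.mask, gibbs)
    assignment = profiles.assign_profiles(summary.map_state)
    profiles.feature_signature(assignment, obs.binarized(), obs.mask)
    contrast_list, table, text = ct.build_report(assignment.labels, obs.period_labels())
    return {
        "schema": schema,
        "templates": templates,
        "records": records,
        "truth": truth,
        "obs": obs,
        "summary": summary,
        "assignment": assignment,
        "contrasts": contrast_list,
        "report_table": table,
        "report_text": text,
    }


def align_signatures(assignment: profiles.ProfileAssignment,
                     templates: list[simulate.ProfileTemplate],
                     top_m: int | None = None) -> tuple[dict[int, int], dict[int, float]]:
    """Best-match recovered profiles to generating templates by signature level.

    Matches the ``top_m`` most prevalent recovered profiles (default: number
    of templates) one-to-one to templates, minimising the summed root-mean-
    square difference between each recovered signature and each template's
    positive-probability vector (NaN signature cells dropped pairwise).
    Level distance, not correlation, drives the matching: templates sharing an
    item-shape but differing in overall severity are only distinguishable by
    level. Returns (template_id -> recovered profile id, template_id ->
    Pearson r of the matched pair).
    """
    top_m = top_m or len(templates)
    rec_ids = list(range(1, top_m + 1))
    cost = np.full((len(templates), top_m), 2.0)   # RMSE on probabilities <= 1
    corr = np.full((len(templates), top_m), np.nan)
    for a, tmpl in enumerate(templates):
        for b, pid in enumerate(rec_ids):
            sig = assignment.signatures.get(pid)
            if sig is None:
                continue
            ok = np.isfinite(sig)
            if ok.sum() < 3:
                continue
            cost[a, b] = float(np.sqrt(np.mean((tmpl.positive_prob[ok] - sig[ok]) ** 2)))
            if np.std(sig[ok]) > 0 and np.std(tmpl.positive_prob[ok]) > 0:
                corr[a, b] = np.corrcoef(tmpl.positive_prob[ok], sig[ok])[0, 1]
    rows, cols = linear_sum_assignment(cost)
    matches = {templates[a].profile_id: rec_ids[b] for a, b in zip(rows, cols)}
    rs = {templates[a].profile_id: float(corr[a, b]) for a, b in zip(rows, cols)}
    return matches, rs


def stacked_signature_r(assignment: profiles.ProfileAssignment,
                        templates: list[simulate.ProfileTemplate],
                        matches: dict[int, int]) -> float:
    """Pearson r between matched recovered signatures and generating templates,
    computed over all (profile, item) cells at once.

    The stacked correlation scores recovery of the whole probability matrix;
    it is robust to the per-cell binomial noise that dominates individual
    low-prevalence profiles (a rare profile contributes few observations per
    item, so its item-wise correlation is noise-limited for any estimator).
    """
    t_cells, s_cells = [], []
    for tmpl in templates:
        sig = assignment.signatures.get(matches[tmpl.profile_id])
        if sig is None:
            continue
        ok = np.isfinite(sig)
        t_cells.append(tmpl.positive_prob[ok])
        s_cells.append(sig[ok])
    return float(np.corrcoef(np.concatenate(t_cells), np.concatenate(s_cells))[0, 1])


# ---------------------------------------------------------------------------
# printed worked examples

#: published period totals and per-profile prevalences (percent)
PUBLISHED_TOTALS = {"pre_lockdown": 960, "lockdown": 214}
PUBLISHED_PREVALENCES = {1: (43.0, 52.8), 2: (17.8, 10.3), 3: (26.7, 34.6), 4: (11.8, 2.3)}
PUBLISHED_RARE_PCT = 0.7


def published_check() -> dict:
    """Recompute the published worked examples from printed inputs alone.

    Reconstructs each profile's 2x2 table from the period totals and printed
    prevalences (counts rounded half away from zero), then computes the
    Yates-corrected chi-square, the percent changes for Profiles 1-3, and the
    exact 95% CI of the pooled rare profiles (7 of 960).
    """
    n_pre, n_lock = PUBLISHED_TOTALS["pre_lockdown"], PUBLISHED_TOTALS["lockdown"]
    out: dict = {"chi2": {}, "p_value": {}, "pct_change": {}, "tables": {}}
    for pid, (pct_pre, pct_lock) in PUBLISHED_PREVALENCES.items():
        a = ct.reconstruct_count(pct_pre, n_pre)
        c = ct.reconstruct_count(pct_lock, n_lock)
        tab = np.array([[a, n_pre - a], [c, n_lock - c]])
        chi2, p = ct.yates_chi_square(tab)
        out["tables"][pid] = tab
        out["chi2"][pid] = chi2
        out["p_value"][pid] = p
        out["pct_change"][pid] = ct.percent_change(pct_pre, pct_lock)
    x_rare = ct.reconstruct_count(PUBLISHED_RARE_PCT, n_pre)
    out["rare_x"] = x_rare
    out["rare_ci"] = ct.clopper_pearson_ci(x_rare, n_pre)
    return out
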