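# Methods

## Data model

The unit of analysis is the *patient-day observation vector*: all answers one
patient gave on one calendar day, standardised to [0, 1] with higher = worse
(positively phrased items are reversed), laid out in fixed schema order
(D = 32). Under the question turn-over design only 2–4 items are observed per
day, so every row carries an explicit observed-entry mask; rows are never
dropped for missingness and nothing is imputed. Repeated answers to the same
item within a day are resolved last-answer-wins (logged). Each row is
labelled `pre_lockdown` (2019-10-01..2020-03-13) or `lockdown`
(2020-03-14..2020-04-14), boundaries inclusive, dates compared in local study
time; rows outside both windows are excluded and counted.

The "responses" the analysis counts (960 pre-lockdown, 214 lockdown) are
patient-day vectors, not individual item answers: 36 patients over ~165 study
days answering 2–4 items per day cannot produce only 960 single answers, and
the vector is the unit the latent-feature model groups.

## Latent-feature model

Observation rows are modelled with an Indian buffet process prior over an
unbounded binary feature-ownership matrix Z (N×K) and a linear-Gaussian
likelihood with weights A (K×D):

    Z ~ IBP(α),  A_kd ~ N(0, σ_A²),  x_id | Z,A ~ N((ZA)_id, σ_X²),

the likelihood taken over observed cells only. Keeping A explicit
(uncollapsed) is what makes the masked likelihood factorise cell-wise; the
collapsed determinant form does not survive row-wise masks. This is the
package's concrete mechanism for handling turn-over missingness.

Gibbs sweep structure, per iteration:

1. each row of Z — existing features by Bernoulli draws with odds
   (m₋ᵢₖ/(N−m₋ᵢₖ)) × likelihood ratio over the row's observed cells; new
   singleton features by a Poisson(α/N) proposal scored with the proposed
   columns' weights integrated out on that row's observed cells (capped at 4
   per step); all-zero columns are retired;
2. A column-wise from its conjugate Gaussian conditional using the rows
   observed at that column (prior fallback when a column is never observed);
3. optionally α from its conjugate posterior Gamma(a + K₊, b + H_N).

The joint log-probability (exchangeable IBP pmf × A prior × masked
likelihood) is traced every iteration and must stay finite. Downstream
analysis uses the retained post-burn-in sample with the highest joint
log-probability (the MAP sample): the study reports one fixed set of
profiles, and label switching across samples makes posterior averaging of Z
ill-defined.

### Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| σ_X | 0.15 | observation noise of standardized scores; matches the score-level noise scale on a unit interval |
| σ_A | 0.5 | feature increments on [0,1] data are fractions of the scale |
| α | 1.0, resampled with Gamma(1,1) | weakly informative; K₊ is data-driven |
| sweeps | 2000 (burn-in 1000, thin 5) library default; 600 (burn-in 300) for the shipped study-scale runs | the study-scale posterior stabilises well before 600 sweeps; the shorter run is the analysis' own size choice |
| init_features | 0 (library), 6 (study-scale runs) | see below |
| max new features/step | 4 | caps the trans-dimensional proposal |

**Warm start.** Under heavy entry-wise missingness the singleton birth move
almost never fires from an empty start: a new feature must justify itself on
a single row's 2–4 observed items, where the attainable likelihood gain
(≲1 nat) cannot offset the log(α/N) prior penalty — even though the same
feature, once owned by many rows, is strongly supported. Initialising the
chain with a handful of random Bernoulli(½) columns leaves the stationary
distribution unchanged and lets the sampler immediately prune or keep
features using evidence pooled across rows.

**Tie-breaking and canonical form.** Feature columns are reported in a
deterministic order (ownership count descending, then the column read as a
binary integer, descending); reordering input rows changes the fit only up to
this relabelling.

## Profiles, signatures, coverage

A *profile* is a distinct feature-activation pattern — a row of the MAP
sample's Z treated as a mutually exclusive label (the all-zero pattern is a
valid baseline profile; K features admit at most 2^K profiles, consistent
with up to 8 profiles reported from a handful of features). Profile ids are
1..P by descending overall prevalence, ties broken by pattern-as-integer. An
alternative labelling (profile = most widely owned active feature) is
available behind a flag.

A profile's *signature* is the empirical per-item probability of scoring
positive (standardized score ≥ 0.5, boundary inclusive) among its rows,
computed over observed entries only; items a profile never observed are
reported missing, never zero. Signatures are empirical rates rather than
model weights because "probability of scoring positive" is well-defined under
any likelihood. *Coverage* of the top m profiles is the sum of their
prevalences.

## Period contrasts

Per profile, rows are cross-classified into a 2×2 table (period ×
in-profile) and tested with the Yates continuity-corrected χ²,

    χ² = n (|ad−bc| − n/2)² / [(a+b)(c+d)(a+c)(b+d)],

correction floored at zero, p from the upper χ²₁ tail. The Yates variant is
adopted because it reproduces all four published statistics
(6.38, 6.69, 5.04, 16.20) from tables reconstructed off the printed period
totals and prevalences (counts rounded half away from zero); the uncorrected
Pearson statistic gives ≈6.80 for Profile 1 and is used only as an upper
bound in tests. Prevalence shifts are signed percent changes relative to the
pre-lockdown prevalence (undefined at zero baseline). Profiles below the
reporting floor (default: outside the top 4) are pooled and summarised with
an exact Clopper–Pearson binomial CI (beta-quantile inversion), which
reproduces the published 0.3–1.5% bounds for 7 of 960. The published "80.1%
decrease" for Profile 4 is not reproducible from the printed prevalences
(11.8 → 2.3 gives 80.5%; presumably computed on unrounded values) and is not
asserted anywhere. P-values are reported to 3 dp, "<0.001" below that. Rows
are treated as independent in the χ² tests although they are nested within
36 patients — this mirrors the source analysis and is a known caveat.

## Synthetic cohort

The generator emulates the study design: 36 patients; per patient-day, 2–4
distinct items drawn uniformly, prompt times uniform in 10.00–22.00 h; a
latent profile drawn i.i.d. per patient-day from the period's mixture
(pre-lockdown 0.430/0.178/0.267/0.118 for Profiles 1–4 with 0.007 spread over
up to four rare low-distinctiveness profiles; lockdown
0.528/0.103/0.346/0.023 with no rare mass); answers are the profile's
severity mean plus N(0, 0.15²) noise, clipped to [0, 1] and mapped back to
the raw item scale. Uniform compliance thinning selects exactly 960
pre-lockdown and 214 lockdown patient-days (the study's row counts) from the
available patient-day grid. Per-patient RNG streams are keyed by
(seed, patient index) so patient-level streams are individually reproducible.

Profile templates are *featural*: severity means are a baseline vector plus
additive increments for a somatic elevation (wish-to-die/sleep/appetite,
shared by Profiles 2 and 4) and a negative-feelings elevation (shared by 3
and 4), matching the study's description of profiles as combinations of
co-occurring symptom groupings; per-item positive probabilities follow from
the means under the noise (P(score ≥ 0.5)), and items alternate between two
levels within each domain so no template is constant. Demographics (age
truncated-normal ≥18 around 41.7/16.3, 86.1% female, Poisson(1.1) prior
attempts) are generated for realism but enter no computation.

What the generator does **not** emulate: within-patient temporal
autocorrelation of profiles (the study notes profiles are dynamic but gives
no dynamics; an i.i.d. redraw per day is the minimal choice), dropout or
differential compliance (thinning is uniform), item-level response styles,
and any real-data deviation from the featural structure. Passing recovery
tests therefore demonstrates the pipeline recovers *this* class of structure
through the turn-over missingness — not that the original clinical findings
are reproduced.

## Numerical and design notes

- Binarization threshold 0.5 (inclusive) on the standardized scale:
  midpoint of a worse-is-higher unit scale; configurable.
- Count reconstruction from printed percentages rounds half away from zero;
  this yields integer tables consistent with all four published χ² values.
- Row updates are done in log space; the sampler aborts on any non-finite
  joint log-probability (never observed in the test battery).
- Written raw values carry 4 decimals, exceeding any plausible instrument
  resolution; table round-trips are exact at that precision.
- Rare remainder profiles are drawn once from a fixed RNG (they are
  constants of the generator, not per-run randomness).

## Known limitations

- **Sampler stickiness on dense data.** With fully observed, strongly
  informative data the uncollapsed sampler can freeze at an inflated K:
  features with many owners cannot die against a strong likelihood, and the
  kernel has no merge/death moves. In the package's operating regime (2–4 of
  32 items observed) the weak per-row likelihood keeps feature birth/death
  mixing adequate. Parameter-recovery tests therefore exercise the masked
  regime; a collapsed or split-merge kernel is the natural v2 extension.
- **Signature noise for rare profiles.** A profile holding ~10% of 1174 rows
  accumulates only ~11 observations per item, so its item-wise signature has
  binomial noise of the same order as the within-profile signal; item-level
  correlation with its generating template is noise-limited for any
  estimator. Recovery is scored on the stacked (all profiles × items)
  signature matrix, which is dominated by between-profile structure.
- Single-chain inference; multi-start or tempering would harden mode
  finding.
- The χ² contrasts ignore within-patient clustering (mirrors the source
  analysis).
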