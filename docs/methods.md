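# Methods

## Synthetic cohort model

The generator emulates a three-cohort cervical-cancer study design: RTBT2
(FIGO stage II, external-beam radiotherapy + brachytherapy, n = 276), RTBT3
(stage III, EBRT+BT, n = 203) and RT3 (stage III, EBRT only, n = 86). A
single latent senescence factor `z ~ N(0, 1)` per patient drives both the
serum panel and the hazard:

* **Analytes.** 19 log2-scale analytes, `x_ij = μ_j + a_j z_i + ε_ij`,
  `ε_ij ~ N(0, σ_j²)` with σ_j = 1 by default. Loadings are a_j = +0.6 for
  the nine senescence-elevated prognostic proteins (CRP, GRO, HGF, MIG,
  MMP1, SAA, SCCA, sIL2Rα, tPAI1), a_j = −0.4 for leptin (prognostic but
  protective), and 0 for the remaining nine. The latent factor induces the
  positive inter-analyte correlation a Luminex SASP panel shows in
  practice.
* **Hazard.** Event times are exponential given covariates
  (constant baseline hazard λ₀ = 0.12 / year):
  `log h = log λ₀ + β_stage·1[III] + β_z·z + g(z)·1[no BT]`, with
  β_stage = ln 2.3 and β_z = ln 1.9 by default. The no-brachytherapy
  effect interpolates logistically in z,
  `g(z) = ln 1.0 + (ln 3.3 − ln 1.0)·expit(k z)` with slope k = 2, so the
  harm of omitting brachytherapy is confined to high-senescence patients
  (at k = 2 the low-senescence stratum carries an average log-HR close to
  0, matching a "no significant benefit" low stratum, while the high
  stratum approaches ln 3.3).
* **Censoring.** Administrative censoring at 5 years plus independent
  exponential loss to follow-up at 0.02 / year — last-visit censoring with
  no stated mechanism is modelled as the simplest independent process.
* Age is drawn (N(49, 10²) clipped to 26–82) but carries no hazard effect:
  the analyses adjust for stage and treatment, not age.

**Effect-size calibration.** A "dichotomized" effect statement — e.g. a
high/low hazard ratio of 3.5 between the top 60% and bottom 40% of the
latent factor — is converted to a per-unit-z coefficient through the
truncated-normal means of the two strata (`with_high_low_hr`). The default
β_z = ln 1.9 implies a 60/40 high/low HR of ≈ 2.8; the ensemble analyses
that presuppose selection-gate-scale effects use the 3.5 calibration and
say so.

**What the generator does not emulate:** plate/batch effects, analyte
missingness, non-proportional hazards, informative censoring,
stage–senescence correlation, and age effects. Tests passing under this
generator demonstrate the pipeline recovers the effects it assumes, not
that those assumptions hold in any real cohort.

## Preprocessing

Replicate CV uses the sample (n−1) standard deviation — replicate groups
are typically pairs. Bead-count threshold defaults to 35 beads/well (an
instrument-level setting; configurable). A well failing both filters is
recorded once, with `low_beads` as the primary reason, and QC is
idempotent. Calibration is a least-squares fit of log2(MFI) on
log2(concentration) — linear by default, quadratic via `degree=2` — chosen
over 4/5-parameter logistic because both axes are log2-transformed before
analysis; a non-monotone fit is rejected rather than inverted. Estimates
outside the standard MFI span are returned but flagged as extrapolated.
Follow-up beyond the 5-year horizon becomes (5.0, censored); a time exactly
at the horizon keeps its event status (censoring applies to *greater than*
5 years).

## Survival engine

Kaplan–Meier, the two-group log-rank test, Cox partial-likelihood
maximization and its L2-penalized variant are implemented directly on
risk-set arithmetic so each can be verified against brute-force oracles
(explicit product-limit enumeration, the tabulated O−E/V computation,
grid-search likelihood maximization) and cross-checked against lifelines.

* **Ties.** Efron's correction by default; Breslow behind a flag for
  oracle cross-checks. Events precede censorings at tied times.
* **Optimization.** Newton–Raphson with step-halving; convergence at
  max|score| < 1e−8 or 50 iterations. A monotone likelihood (separation)
  is detected by coefficient divergence (‖β‖∞ > 15), flagged
  non-converged, capped, and warned about.
* **Inference.** Wald standard errors from the observed information; 95%
  CIs on the log scale; two-sided p-values.
* **Ridge.** Maximizes `pl(β) − λ·m·‖β‖²/2` on covariates standardized to
  zero mean / unit variance at training time, m = number of events —
  scaling the penalty by the effective sample size keeps λ comparable
  across cohort sizes (the glmnet convention). The training
  standardization is stored in the fit and always reused when scoring new
  data; scores are never re-centered at application time. λ = 0 reduces
  exactly to the unpenalized fit.
* **Penalty selection.** Verweij–van Houwelingen cross-validated partial
  deviance, `−2·Σ_k [l_full(β_{−k}) − l_{−k}(β_{−k})]`, over an
  event-stratified K-fold split; folds that would leave a training split
  with zero events are redrawn (≤10 attempts). Grid ties resolve to the
  larger λ (more shrinkage). Standalone default: 50 log-spaced values over
  [1e−3, 1e3], 10 folds. Inside the ensemble's per-split loop the default
  is 8 values over [1e−2, 1e2] with 5 folds — thousands of split fits make
  the full grid disproportionate, and the selected models are insensitive
  to the finer grid.

## Quartile screening

Cutpoints are the 25th/50th/75th percentiles by linear interpolation with
lower-closed assignment (`value ≤ cutpoint` falls low); this uniquely
yields the 145/144/144/145 pattern for 578 distinct values. Ties share a
quartile, so counts may be unequal. The pooled analysis adjusts for stage
and treatment; within-cohort analyses are unadjusted (the adjusters are
constant there, and a constant adjuster raises an error rather than being
dropped silently). Holm adjustment is applied to the Q4 p-values within
each cohort stratum across the 19 proteins; the candidate gate is raw
Q4 p < 0.05 in any stratum.

## Ensemble

Split pairs are event-stratified random partitions into equal halves.
Per-split training: cross-validated λ on the training half only, ridge
fit, score cutoff frozen at the configured percentile of training scores
(empirical inverse-CDF quantile, so exactly ⌈q·n⌉ tie-free scores fall at
or below it; a score exactly at the cutoff goes low). Orientation is
flipped, and recorded, if the above-cutoff group has training HR < 1; it
is flagged unstable when the training contrast is weak (p > 0.05) or when
cross-validation shows no held-out deviance improvement (< 2 units) over
maximal shrinkage — in-sample contrasts are overfit-biased, so the CV
curve carries the evidence of signal.

Selection keeps models with train **and** test HR ≥ 3.0 and both
p ≤ 0.05 (the gate the published model tables imply); the design's
"3000 pairs → ~1000 models" is read as a candidate pool from which the cap
(`max_models`, default 25) retains the best held-out p-values. Bootstrap
validation draws 70% of the cohort *without replacement* (a classical
with-replacement option exists), re-derives the cutoff percentile within
each subsample, and bins the per-draw p-values (>0.05 / 0.05–0.001 /
≤0.001); pass requires ≥95% of draws below 0.05. External validation uses
the frozen cutoff unchanged — the subsample/frozen asymmetry is
deliberate and matches the procedure being reproduced. Validating on the
training cohort raises an error. High-SASP fraction presets: 60% for
RTBT2-optimized models, 40% for RT3-optimized ones.

## Consensus and treatment interaction

Votes are equal-weighted. Binary consensus: high iff strictly more than
50% of models vote high; ternary adds a medium class between the strict
>75% / <25% tails, so boundary fractions resolve downward. Confidence is
the fraction of models agreeing with the plurality call; the
high-confidence summary uses ≥75%.

The brachytherapy contrast pools stage III patients only (mixing stages
would confound the treatment comparison), treats the no-BT arm as exposed
(HR > 1 = benefit of brachytherapy), and reports Wald p by default with
log-rank alongside. Per-model p-values are multiplied by the ensemble size
without capping at 1 — the convention the published adjusted values
follow (0.052 × 25 = 1.30); capped and Holm variants are available. The
observational BT/no-BT comparison is confounded by indication in real
data; it is reproduced as-is.

## Pipeline and reproducibility

One master seed spawns per-stage seeds through `numpy.random.SeedSequence`
so stages can re-run in isolation. All outputs are comma-separated UTF-8
with floats at 6 significant digits; the manifest records config, stage
seeds and SHA-256 of every output, and its overall hash (config minus the
output location + file digests) is bit-stable across re-runs.

## Problem sizes

The checked-in analyses and checks run scaled-down designs chosen to keep
a laptop run in minutes while leaving Monte-Carlo error well inside the
asserted margins: 100–500 split pairs instead of 3000, 200 bootstrap
iterations instead of 1000, 20 cohort draws for the interaction study, and
n = 2000 for closed-form generator checks. The full-scale design remains
the default of `run_ensemble` / `PipelineConfig` (3000 pairs, 1000
bootstraps).

## Known limitations

* The per-split inner CV grid is coarse; λ is a nuisance parameter here
  and the dichotomized score is insensitive to it, but fine-grained
  λ paths should use `cv_lambda_min` directly.
* The logistic-outcome score family (`score_family="logistic"`: ridge
  logistic regression of death-by-5-years) shares the Cox family's λ
  selection rather than using a binomial-deviance CV of its own.
* Only pure-L2 penalties are supported (no elastic-net mixing), matching
  the α = 0 setting the procedure fixes.
* Cohort-level sampling variability is substantial at n = 276 with ~50%
  events: the number of selected models per run ranges from a handful to
  ~20% of split pairs at the same generative effect size.
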