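# saspsurv

Prognostic ensembles of senescence-associated serum proteins for
cervical-cancer survival analysis.

## The problem

Serum levels of senescence-associated secretory phenotype (SASP) proteins —
CRP, SAA, GRO-α, MIG, MMP1, HGF, SCCA, sIL2Rα, PAI-1 and leptin among a
19-analyte multiplex panel — carry prognostic information for
disease-specific survival (DSS) in squamous-cell cervical cancer, and the
benefit of brachytherapy appears concentrated in patients with a high
senescence burden. This package implements the full analysis pipeline for
that question, for biostatisticians working with multiplex serum-protein
panels joined to survival records:

1. **Luminex preprocessing** — bead-count and replicate-CV (>25%) QC,
   log2–log2 standard-curve calibration, concentration estimation, and
   5-year administrative censoring of follow-up.
2. **Quartile screening** — per-protein Cox contrasts of quartiles Q2–Q4
   vs Q1, stage/treatment-adjusted when pooled, Holm-corrected.
3. **Split-pair ridge ensembles** — the core procedure. For each random
   50/50 train/test split of a cohort, fit an L2-penalized Cox score
   `η_i = βᵀ z_i` on the training half (`z_i` standardized log2 protein
   levels, penalty λ chosen by cross-validated partial deviance),
   dichotomize at the 40th percentile of training scores into SASP-low /
   SASP-high, and keep models whose high/low hazard ratio satisfies
   HR ≥ 3 with p ≤ 0.05 in *both* halves. Selected models are validated by
   1000× 70%-subsample bootstrap (cutoff re-derived within each subsample;
   pass = ≥95% of subsamples significant) and by frozen-cutoff application
   to independent cohorts.
4. **Consensus voting** — each model votes SASP-H/L per patient; plurality
   rules classify patients (binary >50%, ternary >75%/<25% with a medium
   class) with per-patient confidence.
5. **Treatment-benefit stratification** — among stage III patients, the
   no-brachytherapy vs brachytherapy hazard ratio within each SASP
   stratum, with uncapped Bonferroni adjustment by ensemble size.

No patient-level data are distributed; a synthetic-cohort generator with a
single latent senescence factor (driving both the analyte panel and the
hazard, with the treatment effect interpolated logistically in the latent
factor) reproduces the study's structure — three stage/treatment-homogeneous
cohorts of 276 / 203 / 86 patients — so every stage is testable end to end.

## Worked example

```bash
python analysis/01_simulate_cohorts.py
python analysis/04_ensemble_models.py
python analysis/06_brachytherapy_interaction.py
```

The last step prints (seed 2024):

```
RT3 ensemble: 25 models selected
Consensus strata, no-BT vs BT (HR > 1 = brachytherapy benefit):
  SASP_L: n(BT/noBT)=114/47 HR=1.63 (1.05-2.51) p=0.028
  SASP_M: n(BT/noBT)=29/12 HR=3.69 (1.67-8.18) p=0.0013
  SASP_H: n(BT/noBT)=60/27 HR=3.10 (1.88-5.09) p=8.41e-06
```

i.e. omitting brachytherapy roughly triples the hazard for high-senescence
stage III patients but has a much weaker effect in the low-senescence
stratum — the generative design places the treatment interaction exactly
there. The multifactor summary that follows orders the stage × SASP ×
treatment categories from worst (stage III, SASP-high, no brachytherapy,
5-year survival ≈ 0–10%) to best (stage II, SASP-low, with brachytherapy,
≈ 60–80%).

The `saspsurv` CLI exposes the same stages
(`saspsurv run-all --seed 1 --outdir results/run`), writing every table
plus a manifest whose hash is reproducible from config + seed.

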