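# radsurv

CT radiomics and survival modelling for EGFR-mutant lung adenocarcinoma
treated with first-line EGFR tyrosine-kinase inhibitors (TKIs).

Patients on EGFR TKIs respond dramatically but almost universally
progress within about a year. `radsurv` is a reusable, tested pipeline
for asking whether quantitative CT features of the tumour — measured at
baseline and at the first follow-up scan — predict progression-free
survival (PFS), and how much they add on top of conventional clinical
factors (age, tumour diameter, RECIST response). It is aimed at
imaging-biomarker researchers who have volume + segmentation pairs and a
clinical outcome table, and at methodologists who want a fully
synthetic, ground-truth-known testbed for this class of analysis.

## What it computes

**37 three-dimensional radiomic features** per volume/mask pair:

| family | features |
|---|---|
| first-order (15) | mean, SD, variance, skewness, kurtosis, entropy, homogeneity, energy, C5–C95 percentiles |
| shape (8) | volume, effective diameter, surface area, sphericity, discrete compactness, compactness 1 and 2, roundness |
| GLCM (5) | moments, angular second moment, inverse difference moment, contrast, entropy |
| GLRL (1) | grey-level nonuniformity (GLN) |
| wavelet (8) | GLN of the 8 stationary-wavelet sub-bands LLL…HHH |

**The analysis cascade**, per the standard prognostic-radiomics design:

1. drop features with inter-reader ICC(2,1) < 0.9 (segmentation
   stability);
2. build three feature sets — baseline, follow-up, percent change
   `100·(FU − base)/base`;
3. group features with Pearson r > 0.95, dichotomize each feature at the
   maximally selected log-rank cutpoint, screen by univariate Cox,
   keep one representative per group;
4. Benjamini–Hochberg adjust and keep the top 4 features;
5. fit radiomic / clinical / combined Cox proportional-hazards models
   (Efron ties) with backward stepwise selection at α = 0.05,
   `HR = exp(β)` with Wald 95 % CIs;
6. compare models by Harrell's concordance index with a 1000-replicate
   patient bootstrap (percentile CIs, paired t-tests) and summarize
   median-linear-predictor risk groups with Kaplan–Meier curves.

A synthetic-data module generates spiculated, textured tumour phantoms,
paired-reader segmentation perturbations, and cohorts whose survival
follows a Cox model with *known* coefficients — so every stage is
testable without any patient data.

## Worked example

Simulate a 48-patient cohort under the package's default study
conditions (median PFS 9.7 months, 20 % censoring, true log hazard
ratios ln 2 on follow-up roundness and ln 1.5 on follow-up GLN) and run
the full analysis:

```bash
radsurv simulate --n 48 --seed 7 --out cohort.csv
radsurv run-all --cohort cohort.csv --seed 7 --bootstrap-b 1000 --out report.json
```

which prints

```
wrote 48 patients to cohort.csv
concordance indices: {'radiomic': 0.758, 'clinical': 0.688, 'combined': 0.785}; report: report.json
```

The JSON report contains every stage. For this seed the top-4 selected
features are the follow-up GLN, follow-up roundness, baseline GLN and
percent-change GLN — i.e. the selection recovered the two truly
prognostic feature families. The fitted models (hazard ratios for the
dichotomized indicators, Wald p):

```
radiomic  c = 0.758 (95% CI 0.663–0.834):
    followup GLN        HR 14.67  p = 0.0001
    followup roundness  HR  5.27  p = 0.0003
    pct-change GLN      HR  2.71  p = 0.027
clinical  c = 0.688 (95% CI 0.586–0.781):
    baseline diameter   HR  1.02 /mm  p = 0.048
    RECIST responder    HR  0.30      p = 0.002
combined  c = 0.785 (95% CI 0.680–0.868)
```

The combined model's concordance exceeds the clinical model's
(bootstrap paired t-test p ≈ 1e-250 over 1000 replicates), reproducing
the qualitative finding this design exists to test: imaging features add
prognostic value over clinical factors alone. Hazard ratios of the
dichotomized indicators are inflated relative to the per-SD generating
values — the expected behaviour of minimum-p dichotomization at n = 48.

The same machinery runs on real data: `radsurv extract` computes the 37
features from NRRD/NIfTI/DICOM volume+mask pairs listed in a manifest
CSV, and `radsurv run-all --schema-map <yaml>` reads any cohort
spreadsheet through a column mapping (see
`data/s1_schema_map.template.yaml`).

## Layout

```
src/radsurv/
  io.py          volumes, masks, cohort tables (NRRD/NIfTI/DICOM, CSV/XLSX)
  features/      discretization, first-order, shape, GLCM/GLRL, wavelet
  stability.py   inter-reader ICC filtering
  selection.py   correlation groups, optimal cutpoints, BH, top-k
  survival.py    Cox fits, stepwise, log-rank, KM, Harrell c, bootstrap
  synthetic.py   phantoms, reader pairs, cohorts with known truth
  pipeline.py    orchestration + validated JSON report schema
  cli.py         radsurv simulate | extract | icc-filter | select | run-all
docs/methods.md  models, conventions, defaults, limitations
```
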