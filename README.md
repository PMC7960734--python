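# remitpredict

Multimodal machine-learning prediction of **remission from alcohol use
disorder (AUD)**: given visit-1 measurements only — resting-state EEG
functional connectivity, polygenic risk scores, demographics and medication
use — predict whether a subject no longer meets AUD criteria at a follow-up
visit years later.

The package is aimed at researchers in psychiatric genetics and EEG
biomarker work who want a tested, reusable implementation of this protocol.
Because the motivating longitudinal cohort is restricted-access, the package
also ships a **synthetic-cohort generator** with recorded ground truth, so
every stage — and the pipeline end to end — can be exercised, validated and
benchmarked without any data access.

## What it computes

**EEG functional connectivity.** For each pair of the 68 Desikan–Killiany
cortical ROIs and each band (theta 4–8, alpha 8–12, beta 12–30, gamma
30–60 Hz, half-open so bands never overlap), the band-averaged
magnitude-squared coherence

```
MSC_ij(f) = |S_ij(f)|² / (S_ii(f) · S_jj(f)) ∈ [0, 1]
```

with Welch-averaged cross-spectra (2 s Hann segments, 50 % overlap by
default). 68 ROIs × 4 bands → 9112 named features per subject.

**Polygenic risk scores.** Clumping + thresholding from discovery GWAS
summary statistics: greedy LD clumping keeps the most significant SNP of
each correlated group (r² ≥ 0.25 within a 500 kb window, against a reference
panel), then one score per p-value cutoff t ∈ {1e-4, 1e-3, 0.01, 0.05, 0.1,
0.2, 0.3, 0.4, 0.5}:

```
PRS_t = Σ_{p_snp < t} sign(β_snp) · (−log10 p_snp) · dosage_snp
```

Z-standardized per column. Genetic ancestry (EA/AA) is assigned by PCA of
the standardized genotype matrix followed by 2-means clustering of PC1/PC2,
anchored to self-report by majority vote.

**Cohort assembly.** Sex × ancestry stratification (self-reported or genetic
ancestry), greedy 1:1 age matching of the remitted and continued groups
(2-year caliper by default), listwise deletion per feature set, and
Z-normalization with a fit/transform split for leakage-free CV.

**Classifier.** LASSO (squared-error loss on the ±1-coded label, penalty by
10-fold CV over a log grid from λ_max) selects the nonzero-coefficient
features; a soft-margin linear SVM (hinge + L2, C tuned by inner 5-fold CV)
classifies; evaluation is shuffled **stratified 10-fold CV repeated 10
times** (mean ± SD across repeats) plus an optional 70:30 holdout. Metrics:
accuracy, sensitivity (remitted recall), specificity (continued recall), and
rank-based (Mann–Whitney) AUC.

Two evaluation modes exist, deliberately:

* `paper_faithful` — Z-normalize and LASSO-select **once on the full
  stratum**, then cross-validate the SVM. This reproduces the published
  order of operations but lets held-out folds influence feature selection.
* `nested` — normalization and selection refit **inside every training
  fold**; the honest generalization estimate.

On pure-noise data (n = 100, 5000 features) `paper_faithful` scores tens of
points above the 50 % truth while `nested` stays at chance — the
fidelity-vs-validity trade-off is quantified by the acceptance script
(`leakage_margin_pct`) and demonstrated in `examples/06_leakage_modes.py`.
Report nested-mode scores when claiming generalization.

## Worked example

`examples/05_crossvalidated_model.py` simulates a 120-subject cohort with a
planted theta-coherence gap (0.15 vs 0.6), one causal SNP and a marriage
effect, assembles the EA-male stratum, age-matches and runs nested repeated
CV. It prints:

```
stratum EA male: 48 subjects after age matching (24 matched pairs), 79 features

                         Model Specificity (%) Sensitivity (%) Accuracy (%)        AUC
EA male (EEG+PRS+demographics)     99.00 ± 2.2    100.00 ± 0.0  99.56 ± 1.0 1.00 ± 0.0

top selected features (SVM |weight| rank):
    lh_bankssts-lh_caudalanteriorcingulate@theta  EEG  0.835  1  theta ... lower
```

The planted ROI pair tops the feature ranking (rank 1 = largest |SVM
weight|), its direction column says theta coherence is *lower* in the
continued-AUD group (as planted: 0.15 vs 0.6), and the near-perfect accuracy
reflects the strong planted effect evaluated without selection leakage. The
other examples cover each capability in isolation: cohort simulation,
coherence features, PRS scoring, ancestry PCA, and the leakage comparison.

A thin CLI wraps the same library calls:

```bash
remitpredict simulate --config cohort.yaml --out data/ --seed 7
remitpredict eeg-fc --signals data/roi_signals.h5 --out fc.csv
remitpredict run --config pipeline.yaml
```

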