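"""End-to-end stratified model: assemble, age-match, LASSO->SVM repeated CV.

Simulates a multimodal cohort with planted effects in all three modalities,
builds the combined feature table, restricts it to one sex x ancestry stratum,
age-matches the outcome groups, and evaluates the classifier with nested
(leakage-free) repeated cross-validation. Prints the results table and the
top-ranked discriminative features.
"""

import numpy as np

from remitpredict import (
    CausalSnp,
    CoherenceEffect,
    CohortTruth,
    StratumSpec,
    age_match,
    build_feature_table,
    coherence_features,
    complete_cases,
    generate_cohort,
    prs_feature_block,
    render_feature_report,
    render_results_table,
    repeated_cv_evaluate,
    stratify,
)

truth = CohortTruth(
    n_per_group=60,
    coherence_effects=[CoherenceEffect(0, 1, "theta", 0.15, 0.6)],
    causal_snps=[CausalSnp("rs_effect", "A", 0.9)],
    covariate_effects={"married": -1.0},
    seed=19,
)
cohort = generate_cohort(
    truth, n_rois=6, fs=128.0, duration=40.0, n_snps=40, n_blocks=8, block_r2=0.4
)

eeg = coherence_features(cohort.signals)
prs = prs_feature_block(
    cohort.genotypes, {"prs": cohort.summary_stats}, cohort.reference_panel
)
table = build_feature_table([("EEG", eeg.features), ("PRS", prs)], cohort.subjects)

stratum = stratify(table, StratumSpec("male", "EA"))
stratum = complete_cases(stratum)
stratum, pairs = age_match(stratum, caliper=5.0)
print(f"stratum EA male: {len(stratum.features)} subjects after age matching "
      f"({len(pairs)} matched pairs), {stratum.features.shape[1]} features")

result = repeated_cv_evaluate(
    stratum, mode="nested", outer_folds=5, repeats=5, seed=19,
    lasso_kwargs={"n_folds": 5, "n_alphas": 40, "alpha_min_ratio": 0.01},
    label="EA male (EEG+PRS+demographics)",
)
print()
print(render_results_table([result]).to_string(index=False))
print()
print("top selected features (SVM |weight| rank):")
report = render_feature_report(result)
print(report.head(8).to_string(index=False))
print()
print("the planted theta pair carries most of the signal and tops the "
      "ranking; accuracy well above 50% reflects the planted effects, not "
      "leakage (selection was refit inside every training fold)")
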