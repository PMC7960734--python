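"""Clumping + thresholding polygenic scores from summary statistics.

Simulates LD-blocked genotypes with one causal SNP, clumps the summary
statistics against the reference panel (r² ≥ 0.25 within 500 kb), scores the
nine standard p-value thresholds, and shows that the standardized score at the
strictest threshold separates the outcome groups.
"""

import pandas as pd

from remitpredict import clump, prs_scores, standardize_prs
from remitpredict.synthetic_cohort import CausalSnp, simulate_genetics

labels = {f"S{i:03d}": ("remitted" if i % 2 else "continued") for i in range(300)}
genotypes, stats, reference = simulate_genetics(
    labels, [CausalSnp("rs_causal", "A", 0.6)],
    n_snps=60, n_blocks=12, block_r2=0.5, seed=5,
)

retained = clump(stats, reference, r2_threshold=0.25, window_kb=500)
print(f"clumping kept {len(retained)}/{len(stats.snp_ids)} SNPs "
      "(one index SNP per LD block)")

prs = standardize_prs(prs_scores(genotypes, stats, retained))
print(f"score matrix: {prs.scores.shape[0]} subjects x {prs.scores.shape[1]} thresholds")

lab = pd.Series(labels)
col = prs.scores["score@0.0001"]
gap = col[lab == "remitted"].mean() - col[lab == "continued"].mean()
print(f"standardized PRS gap at p<1e-4 (remitted - continued): {gap:+.2f} SD")
print("a positive gap means the score built from the planted risk allele is "
      "higher among remitters, matching the simulated direction")
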