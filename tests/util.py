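"""Independent reference implementations used as oracles in the tests.

These deliberately re-derive results from first principles (brute force,
literal replay of a procedure's definition) and never call the code paths
they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from remitpredict.genetics import GenotypeMatrix, SummaryStatsTable


def brute_force_clump(
    stats: SummaryStatsTable,
    reference: GenotypeMatrix,
    r2_threshold: float = 0.25,
    window_kb: float = 500.0,
) -> set[str]:
    """Literal replay of greedy clumping on explicit pairwise r2 values."""
    t = stats.table.set_index("snp")
    remaining = list(
        t.sort_values(["p", "chr", "pos"], kind="mergesort")
        .sort_index(kind="mergesort")
        .sort_values(["p", "chr", "pos"], kind="mergesort")
        .index
    )
    # deterministic tie order: (p, chr, pos, id)
    remaining = sorted(t.index, key=lambda s: (t.at[s, "p"], t.at[s, "chr"], t.at[s, "pos"], s))

    def r2(a: str, b: str) -> float:
        da = reference.dosages[a].to_numpy(dtype=float)
        db = reference.dosages[b].to_numpy(dtype=float)
        ok = ~(np.isnan(da) | np.isnan(db))
        da, db = da[ok], db[ok]
        if da.var() == 0 or db.var() == 0:
            return 0.0
        return float(np.corrcoef(da, db)[0, 1] ** 2)

    retained: set[str] = set()
    while remaining:
        index_snp = remaining.pop(0)
        retained.add(index_snp)
        if index_snp not in reference.dosages.columns:
            continue
        survivors = []
        for s in remaining:
            same_chr = t.at[s, "chr"] == t.at[index_snp, "chr"]
            close = abs(t.at[s, "pos"] - t.at[index_snp, "pos"]) <= window_kb * 1000
            in_ref = s in reference.dosages.columns
            if same_chr and close and in_ref and r2(index_snp, s) >= r2_threshold:
                continue  # clumped away
            survivors.append(s)
        remaining = survivors
    return retained


def brute_force_auc(y01: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the exhaustive pairwise win count with half credit for ties."""
    pos = scores[y01 == 1]
    neg = scores[y01 == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (len(pos) * len(neg)))


def random_clump_instance(rng: np.random.Generator, max_snps: int = 12):
    """A random small clumping problem: stats table + reference panel."""
    n_snps = int(rng.integers(1, max_snps + 1))
    n_ref = 40
    ids = [f"s{i}" for i in range(n_snps)]
    chrs = rng.choice(["1", "2"], size=n_snps)
    pos = rng.integers(1, 2_000_000, size=n_snps)
    # correlated groups: mix a few latent factors so some pairs clump
    latent = rng.standard_normal((n_ref, 3))
    loadings = rng.integers(0, 3, size=n_snps)
    mix = rng.uniform(0, 1, size=n_snps)
    raw = (
        mix * latent[:, loadings]
        + (1 - mix) * rng.standard_normal((n_ref, n_snps))
    )
    dosages = np.clip(np.round(raw - raw.min(axis=0)), 0, 2)
    stats = SummaryStatsTable(
        pd.DataFrame(
            {
                "snp": ids,
                "chr": chrs,
                "pos": pos,
                "a1": "A",
                "a2": "G",
                "beta": rng.standard_normal(n_snps),
                "p": rng.uniform(1e-8, 1, size=n_snps),
            }
        )
    )
    info = stats.table.set_index("snp")[["chr", "pos", "a1", "a2"]]
    ref = GenotypeMatrix(
        pd.DataFrame(dosages, index=[f"r{i}" for i in range(n_ref)], columns=ids), info
    )
    return stats, ref
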