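"""PRS machinery: LD r2, clumping vs brute force, scoring, standardization, PCA."""

import numpy as np
import pandas as pd
import pytest

from remitpredict.genetics import (
    DEFAULT_THRESHOLDS,
    GenotypeMatrix,
    PrsMatrix,
    SummaryStatsTable,
    ancestry_pca,
    assign_ancestry,
    clump,
    ld_r2,
    prs_scores,
    snp_weights,
    standardize_prs,
)
from util import brute_force_clump, random_clump_instance


def _geno(dosage_cols: dict, pos=None, chrs=None) -> GenotypeMatrix:
    ids = list(dosage_cols)
    n = len(next(iter(dosage_cols.values())))
    info = pd.DataFrame(
        {
            "chr": chrs if chrs is not None else ["1"] * len(ids),
            "pos": pos if pos is not None else np.arange(1, len(ids) + 1),
            "a1": "A",
            "a2": "G",
        },
        index=pd.Index(ids, name="snp"),
    )
    dos = pd.DataFrame(dosage_cols, index=[f"p{i}" for i in range(n)], dtype=float)
    return GenotypeMatrix(dos, info)


class TestLdR2:
    def test_self_pair_is_one(self):
        g = _geno({"a": [0, 1, 2, 0]})
        assert ld_r2(g, "a", "a") == 1.0

    def test_perfect_anticorrelation_squares_to_one(self):
        g = _geno({"a": [0, 1, 2, 0], "b": [2, 1, 0, 2]})
        assert ld_r2(g, "a", "b") == pytest.approx(1.0)

    def test_monomorphic_snp_gives_zero_with_warning(self):
        g = _geno({"a": [1, 1, 1, 1], "b": [0, 1, 2, 0]})
        with pytest.warns(UserWarning, match="monomorphic"):
            assert ld_r2(g, "a", "b") == 0.0

    def test_missing_dosages_use_complete_pairs(self):
        g = _geno({"a": [0, 1, 2, np.nan], "b": [0, 1, 2, 0]})
        assert ld_r2(g, "a", "b") == pytest.approx(1.0)


class TestClump:
    def test_hand_worked_four_snp_example(self):
        """Greedy clumping keeps SNP1 (index), drops SNP2 (close + correlated),
        keeps SNP3 (close but uncorrelated) and SNP4 (correlated but outside
        the 500 kb window)."""
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=60).astype(float)
        noise = rng.integers(0, 3, size=60).astype(float)
        g = _geno(
            {"SNP1": base, "SNP2": base, "SNP3": noise, "SNP4": base},
            pos=[100_000, 200_000, 300_000, 700_000],
        )
        assert ld_r2(g, "SNP1", "SNP2") >= 0.25
        assert ld_r2(g, "SNP1", "SNP3") < 0.25
        stats = SummaryStatsTable(
            pd.DataFrame(
                {
                    "snp": ["SNP1", "SNP2", "SNP3", "SNP4"],
                    "chr": "1",
                    "pos": [100_000, 200_000, 300_000, 700_000],
                    "a1": "A",
                    "a2": "G",
                    "beta": 0.1,
                    "p": [1e-6, 1e-5, 1e-4, 0.2],
                }
            )
        )
        assert set(clump(stats, g)) == {"SNP1", "SNP3", "SNP4"}

    def test_single_snp_retained(self):
        g = _geno({"only": [0, 1, 2, 1]})
        stats = SummaryStatsTable(
            pd.DataFrame(
                {"snp": ["only"], "chr": "1", "pos": [10], "a1": "A", "a2": "G",
                 "beta": [1.0], "p": [0.5]}
            )
        )
        assert clump(stats, g) == ["only"]

    def test_empty_stats_empty_list(self):
        g = _geno({"a": [0, 1, 2, 0]})
        stats = SummaryStatsTable(
            pd.DataFrame(columns=["snp", "chr", "pos", "a1", "a2", "beta", "p"])
        )
        assert clump(stats, g) == []

    def test_absent_reference_snp_retained_with_warning(self):
        g = _geno({"a": [0, 1, 2, 0]})
        stats = SummaryStatsTable(
            pd.DataFrame(
                {"snp": ["a", "ghost"], "chr": "1", "pos": [10, 20], "a1": "A",
                 "a2": "G", "beta": [0.1, 0.2], "p": [0.01, 0.001]}
            )
        )
        with pytest.warns(UserWarning, match="absent"):
            assert set(clump(stats, g)) == {"a", "ghost"}

    def test_matches_brute_force_on_random_instances(self):
        """Greedy output equals a literal replay of the definition."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            stats, ref = random_clump_instance(rng)
            assert set(clump(stats, ref)) == brute_force_clump(stats, ref)


class TestPrsScores:
    def _two_snp_setup(self):
        g = _geno({"s1": [2.0], "s2": [1.0]})
        g.dosages.index = ["subj"]
        stats = SummaryStatsTable(
            pd.DataFrame(
                {"snp": ["s1", "s2"], "chr": "1", "pos": [100, 200], "a1": "A",
                 "a2": "G", "beta": [0.3, 0.2], "p": [1e-4, 0.01]}
            )
        )
        return g, stats

    def test_hand_computed_scores(self):
        """-log10(1e-4)*2 = 8 below t=0.001; +(-log10(0.01))*1 = 10 at t=0.05."""
        g, stats = self._two_snp_setup()
        prs = prs_scores(g, stats, ["s1", "s2"], thresholds=[0.001, 0.05])
        assert prs.scores.loc["subj", "score@0.001"] == pytest.approx(8.0)
        assert prs.scores.loc["subj", "score@0.05"] == pytest.approx(10.0)

    def test_zero_dosages_zero_scores(self):
        g = _geno({"s1": [0.0, 0.0], "s2": [0.0, 0.0]})
        _, stats = self._two_snp_setup()
        prs = prs_scores(g, stats, ["s1", "s2"])
        assert (prs.scores.to_numpy() == 0).all()

    def test_threshold_nesting_monotone_for_positive_weights(self, rng):
        n_snps = 30
        stats = SummaryStatsTable(
            pd.DataFrame(
                {"snp": [f"v{i}" for i in range(n_snps)], "chr": "1",
                 "pos": np.arange(1, n_snps + 1) * 1000, "a1": "A", "a2": "G",
                 "beta": rng.uniform(0.01, 1, n_snps), "p": rng.uniform(0, 1, n_snps)}
            )
        )
        g = _geno({f"v{i}": rng.integers(0, 3, 50).astype(float) for i in range(n_snps)})
        prs = prs_scores(g, stats, stats.snp_ids, DEFAULT_THRESHOLDS)
        vals = prs.scores.to_numpy()
        assert np.all(np.diff(vals, axis=1) >= -1e-12)

    def test_scoring_linearity(self, rng):
        _, stats = self._two_snp_setup()
        a = {"s1": [1.0], "s2": [0.0]}
        b = {"s1": [1.0], "s2": [1.0]}
        ab = {"s1": [2.0], "s2": [1.0]}
        scores = [
            prs_scores(_geno(d), stats, ["s1", "s2"], [0.05]).scores.iloc[0, 0]
            for d in (a, b, ab)
        ]
        assert scores[0] + scores[1] == pytest.approx(scores[2])

    def test_allele_flip_invariance(self):
        """Swapping A1/A2 with d -> 2-d and beta -> -beta shifts every score by
        a constant, leaving standardized scores unchanged."""
        rng = np.random.default_rng(5)
        dos = rng.integers(0, 3, 20).astype(float)
        g1 = _geno({"s": dos, "t": rng.integers(0, 3, 20).astype(float)})
        g2 = _geno({"s": 2 - dos, "t": g1.dosages["t"].to_numpy()})
        stats1 = SummaryStatsTable(
            pd.DataFrame({"snp": ["s", "t"], "chr": "1", "pos": [1, 2], "a1": "A",
                          "a2": "G", "beta": [0.4, -0.2], "p": [0.01, 0.02]})
        )
        stats2 = SummaryStatsTable(stats1.table.assign(beta=[-0.4, -0.2]))
        z1 = standardize_prs(prs_scores(g1, stats1, ["s", "t"], [0.05]))
        z2 = standardize_prs(prs_scores(g2, stats2, ["s", "t"], [0.05]))
        np.testing.assert_allclose(z1.scores.to_numpy(), z2.scores.to_numpy(), atol=1e-9)

    def test_empty_threshold_set_rejected(self):
        g, stats = self._two_snp_setup()
        with pytest.raises(ValueError, match="empty"):
            prs_scores(g, stats, ["s1"], thresholds=[])

    def test_weights_are_signed_neglog10(self):
        _, stats = self._two_snp_setup()
        w = snp_weights(stats)
        assert w["s1"] == pytest.approx(4.0)
        neg = SummaryStatsTable(stats.table.assign(beta=[-0.3, 0.2]))
        assert snp_weights(neg)["s1"] == pytest.approx(-4.0)


class TestStandardize:
    def _prs(self, col):
        return PrsMatrix(pd.DataFrame({"x@0.05": col}), (0.05,), False)

    def test_simple_column(self):
        z = standardize_prs(self._prs([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z.scores["x@0.05"], [-1, 0, 1])

    def test_idempotent(self):
        once = standardize_prs(self._prs([4.0, -1.0, 2.5, 0.0]))
        twice = standardize_prs(once)
        np.testing.assert_allclose(
            once.scores.to_numpy(), twice.scores.to_numpy(), atol=1e-12
        )

    def test_moments_and_flags(self, rng):
        z = standardize_prs(self._prs(rng.normal(5, 3, 40)))
        assert z.standardized
        assert z.scores["x@0.05"].mean() == pytest.approx(0.0, abs=1e-9)
        assert z.scores["x@0.05"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_column_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            z = standardize_prs(self._prs([2.0, 2.0, 2.0]))
        assert (z.scores.to_numpy() == 0).all()

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            standardize_prs(self._prs([1.0]))


def _two_population_genotypes(rng, n=200, m=200, divergence=0.25):
    f1 = rng.uniform(0.1, 0.5, m)
    f2 = np.clip(f1 + divergence * np.sign(rng.standard_normal(m)), 0.05, 0.95)
    pop = np.repeat([0, 1], n // 2)
    dos = np.where(
        pop[:, None] == 0, rng.binomial(2, f1, (n, m)), rng.binomial(2, f2, (n, m))
    ).astype(float)
    info = pd.DataFrame(
        {"chr": "1", "pos": np.arange(1, m + 1), "a1": "A", "a2": "G"},
        index=pd.Index([f"v{i}" for i in range(m)], name="snp"),
    )
    g = GenotypeMatrix(
        pd.DataFrame(dos, index=[f"p{i}" for i in range(n)], columns=info.index), info
    )
    truth = pd.Series(np.where(pop == 0, "EA", "AA"), index=g.dosages.index)
    return g, truth


class TestAncestry:
    def test_pc1_separates_divergent_populations(self, rng):
        g, truth = _two_population_genotypes(rng)
        pca = ancestry_pca(g)
        assigned = assign_ancestry(pca, truth, seed=0)
        assert (assigned == truth).mean() >= 0.99

    def test_pcs_are_orthogonal(self, rng):
        g, _ = _two_population_genotypes(rng, n=60, m=120)
        coords = ancestry_pca(g, n_components=5).coords.to_numpy()
        gram = coords.T @ coords
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_identical_genotypes_error(self):
        dos = pd.DataFrame(np.ones((5, 10)), columns=[f"v{i}" for i in range(10)])
        info = pd.DataFrame(
            {"chr": "1", "pos": np.arange(10) + 1, "a1": "A", "a2": "G"},
            index=dos.columns,
        )
        with pytest.raises(ValueError, match="polymorphic"):
            ancestry_pca(GenotypeMatrix(dos, info))

    def test_relabeling_flips_names_not_partition(self, rng):
        g, truth = _two_population_genotypes(rng, n=100, m=150)
        pca = ancestry_pca(g)
        a = assign_ancestry(pca, truth, seed=0)
        flipped = truth.map({"EA": "AA", "AA": "EA"})
        b = assign_ancestry(pca, flipped, seed=0)
        assert ((a == "EA") == (b == "AA")).all()

    def test_single_population_flagged(self, rng):
        g, truth = _two_population_genotypes(rng, n=100, m=150, divergence=0.0)
        pca = ancestry_pca(g)
        with pytest.warns(UserWarning, match="degenerate"):
            assign_ancestry(pca, truth, seed=0)

    def test_k_not_two_unsupported(self, rng):
        g, truth = _two_population_genotypes(rng, n=40, m=60)
        with pytest.raises(ValueError, match="k=2"):
            assign_ancestry(ancestry_pca(g), truth, k=3)
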