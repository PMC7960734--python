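"""Polygenic risk scoring by clumping + p-value thresholding, and genotype PCA.

A polygenic risk score (PRS) summarizes a subject's genetic liability for a
trait as a weighted sum of trait-associated allele dosages. Discovery GWAS
summary statistics supply per-SNP effect directions and p-values; linkage
disequilibrium (LD) clumping prunes each physically proximal, correlated group
of SNPs down to its most significant member (r² >= 0.25 within a 500 kb window
by default), and a family of scores is built at nine nested p-value cutoffs
(p < 1e-4 ... p < 0.5). Each retained SNP is weighted by
``sign(beta) * (-log10 p)``; scores are Z-standardized per column.

Ancestry is inferred from the genotype matrix itself: SNP-wise standardized
dosages (center 2f, scale sqrt(2 f (1-f))) are decomposed into principal
components, whose leading axes separate continental ancestry groups; a
2-means clustering of the first two PCs then dichotomizes subjects into
EA/AA (European/African ancestry) groups anchored to self-report by majority
vote.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStatsTable",
    "GenotypeMatrix",
    "PrsMatrix",
    "PcaResult",
    "DEFAULT_THRESHOLDS",
    "ld_r2",
    "clump",
    "prs_scores",
    "standardize_prs",
    "prs_feature_block",
    "ancestry_pca",
    "assign_ancestry",
]

#: The nine GWAS p-value cutoffs used to build the score family.
DEFAULT_THRESHOLDS: tuple[float, ...] = (
    1e-4, 1e-3, 1e-2, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50,
)

SUMSTATS_COLUMNS = ["snp", "chr", "pos", "a1", "a2", "beta", "p"]


@dataclasses.dataclass
class SummaryStatsTable:
    """Per-SNP discovery GWAS statistics.

    ``table`` columns: snp, chr, pos (1-based bp), a1 (effect allele),
    a2 (other allele), beta, p.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary stats missing columns: {missing}")
        t = self.table
        if t["snp"].duplicated().any():
            dups = t.loc[t["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate SNP ids: {dups[:5]}")
        if not ((t["p"] > 0) & (t["p"] <= 1)).all():
            raise ValueError("p-values must lie in (0, 1]")
        if not (t["pos"] > 0).all():
            raise ValueError("positions must be positive (1-based)")

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp"].tolist()

    @classmethod
    def from_tsv(cls, path) -> "SummaryStatsTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"chr": str}))

    def to_tsv(self, path) -> None:
        self.table[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class GenotypeMatrix:
    """Subjects x SNPs effect-allele dosages in [0, 2] (NaN = missing).

    ``dosages`` is a DataFrame indexed by subject id with SNP-id columns;
    ``snp_info`` is indexed by SNP id with columns chr, pos, a1, a2.
    """

    dosages: pd.DataFrame
    snp_info: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.columns.duplicated().any():
            raise ValueError("duplicate SNP ids in genotype matrix")
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        missing = set(self.dosages.columns) - set(self.snp_info.index)
        if missing:
            raise ValueError(f"snp_info missing entries for {sorted(missing)[:5]}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @classmethod
    def from_tsv(cls, dosage_path, snp_info_path) -> "GenotypeMatrix":
        dos = pd.read_csv(dosage_path, sep="\t", index_col=0)
        info = pd.read_csv(snp_info_path, sep="\t", index_col=0, dtype={"chr": str})
        return cls(dos, info)

    def to_tsv(self, dosage_path, snp_info_path=None) -> None:
        self.dosages.to_csv(dosage_path, sep="\t")
        if snp_info_path is not None:
            self.snp_info.to_csv(snp_info_path, sep="\t")


@dataclasses.dataclass
class PrsMatrix:
    """Subjects x (phenotype @ threshold) polygenic scores."""

    scores: pd.DataFrame  # columns "phenotype@threshold"
    thresholds: tuple[float, ...]
    standardized: bool = False


def ld_r2(reference: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of dosages over subjects complete for both SNPs."""
    if snp_a == snp_b:
        return 1.0
    a = reference.dosages[snp_a].to_numpy(dtype=float)
    b = reference.dosages[snp_b].to_numpy(dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise ValueError(f"fewer than 2 complete observations for pair ({snp_a}, {snp_b})")
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        warnings.warn(
            f"monomorphic SNP in pair ({snp_a}, {snp_b}); r2 defined as 0", stacklevel=2
        )
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(
    stats: SummaryStatsTable,
    reference: GenotypeMatrix,
    r2_threshold: float = 0.25,
    window_kb: float = 500.0,
) -> list[str]:
    """Greedy LD clumping: keep the most significant SNP of each correlated group.

    Repeatedly take the not-yet-clumped SNP with the smallest p-value as an
    index SNP; every other unclumped SNP on the same chromosome within
    ±window_kb whose r² with the index is >= r2_threshold is removed. Ties on
    p break by (chr, pos) then id. SNPs absent from the reference panel cannot
    be clumped (their LD is unknown) and are retained with a warning.

    Returns retained SNP ids in index (ascending-p) order.
    """
    t = stats.table
    if t.empty:
        return []
    order = t.sort_values(["p", "chr", "pos", "snp"], kind="mergesort")
    absent = [s for s in order["snp"] if s not in reference.dosages.columns]
    if absent:
        warnings.warn(
            f"{len(absent)} SNP(s) absent from the reference panel are retained "
            f"unclumped (e.g. {absent[:3]})",
            stacklevel=2,
        )
    absent_set = set(absent)
    window_bp = window_kb * 1000.0

    snps = order["snp"].to_numpy()
    chrs = order["chr"].to_numpy()
    poss = order["pos"].to_numpy(dtype=float)
    removed = np.zeros(len(snps), dtype=bool)
    retained: list[str] = []
    for i in range(len(snps)):
        if removed[i]:
            continue
        retained.append(snps[i])
        if snps[i] in absent_set:
            continue
        near = (
            ~removed
            & (chrs == chrs[i])
            & (np.abs(poss - poss[i]) <= window_bp)
        )
        near[: i + 1] = False  # only less-significant SNPs can be removed
        for j in np.flatnonzero(near):
            if snps[j] in absent_set:
                continue
            if ld_r2(reference, snps[i], snps[j]) >= r2_threshold:
                removed[j] = True
    return retained


def snp_weights(stats: SummaryStatsTable) -> pd.Series:
    """Per-SNP score weight: sign(beta) * (-log10 p), indexed by SNP id."""
    t = stats.table
    w = np.sign(t["beta"].to_numpy()) * (-np.log10(t["p"].to_numpy()))
    return pd.Series(w, index=t["snp"].to_numpy())


def prs_scores(
    genotypes: GenotypeMatrix,
    stats: SummaryStatsTable,
    retained: Sequence[str],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    phenotype: str = "score",
) -> PrsMatrix:
    """Raw clumping+thresholding scores at each p-value cutoff.

    For cutoff t the score is sum over retained SNPs with p < t (strict) of
    weight * dosage; missing dosages are mean-imputed per SNP first. Because
    the SNP sets are nested in t, with all-positive weights the per-subject
    scores are non-decreasing in t.
    """
    if len(thresholds) == 0:
        raise ValueError("threshold set is empty")
    retained = list(retained)
    unknown = set(retained) - set(stats.snp_ids)
    if unknown:
        raise ValueError(f"retained SNPs not in summary stats: {sorted(unknown)[:5]}")
    scorable = [s for s in retained if s in genotypes.dosages.columns]
    if len(scorable) < len(retained):
        warnings.warn(
            f"{len(retained) - len(scorable)} retained SNP(s) not genotyped; skipped",
            stacklevel=2,
        )
    sub = stats.table.set_index("snp").loc[scorable]
    weights = snp_weights(stats)[scorable]
    dos = genotypes.dosages[scorable].to_numpy(dtype=float)
    col_mean = np.nanmean(dos, axis=0) if dos.size else np.zeros(0)
    if dos.size:
        nan_mask = np.isnan(dos)
        dos = np.where(nan_mask, np.broadcast_to(col_mean, dos.shape), dos)

    cols = {}
    pvals = sub["p"].to_numpy()
    w = weights.to_numpy()
    for t in thresholds:
        use = pvals < t
        cols[f"{phenotype}@{t:g}"] = dos[:, use] @ w[use] if use.any() else np.zeros(len(genotypes.subject_ids))
    scores = pd.DataFrame(cols, index=genotypes.dosages.index)
    scores.index.name = "subject_id"
    return PrsMatrix(scores=scores, thresholds=tuple(thresholds), standardized=False)


def standardize_prs(raw: PrsMatrix) -> PrsMatrix:
    """Z-score each score column (mean 0, sample sd 1, ddof=1).

    Constant columns are set to 0 with a warning; a single-subject matrix is
    an error because a sample standard deviation is undefined.
    """
    if len(raw.scores) < 2:
        raise ValueError("standardization requires at least 2 subjects")
    mu = raw.scores.mean(axis=0)
    sd = raw.scores.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"constant PRS column(s) set to 0: {list(raw.scores.columns[const])}",
            stacklevel=2,
        )
    sd = sd.where(~const, 1.0)
    z = (raw.scores - mu) / sd
    z.loc[:, const] = 0.0
    return PrsMatrix(scores=z, thresholds=raw.thresholds, standardized=True)


def prs_feature_block(
    genotypes: GenotypeMatrix,
    stats_by_phenotype: Mapping[str, SummaryStatsTable],
    reference: GenotypeMatrix,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    r2_threshold: float = 0.25,
    window_kb: float = 500.0,
    standardize: bool = True,
) -> pd.DataFrame:
    """Clump, score and (optionally) standardize one PRS family per phenotype.

    Convenience wrapper producing the subjects x "phenotype@threshold" feature
    block consumed by cohort assembly.
    """
    blocks = []
    for name, stats in stats_by_phenotype.items():
        retained = clump(stats, reference, r2_threshold=r2_threshold, window_kb=window_kb)
        prs = prs_scores(genotypes, stats, retained, thresholds, phenotype=name)
        if standardize:
            prs = standardize_prs(prs)
        blocks.append(prs.scores)
    return pd.concat(blocks, axis=1)


@dataclasses.dataclass
class PcaResult:
    """Genotype principal components: subject coordinates and variance shares."""

    coords: pd.DataFrame  # subjects x PC1..PCk
    explained_variance_ratio: np.ndarray
    n_monomorphic_dropped: int


def ancestry_pca(genotypes: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of the standardized genotype matrix.

    Dosages are centered by 2f and scaled by sqrt(2 f (1-f)) per SNP, where f
    is the sample allele frequency of the effect allele; monomorphic SNPs are
    dropped (logged in the result). The subject x subject covariance is then
    eigendecomposed. Sign convention: the largest-magnitude coordinate of each
    PC is positive.
    """
    X = genotypes.dosages.to_numpy(dtype=float)
    n_subj, n_snp = X.shape
    if n_subj < 2:
        raise ValueError("PCA requires at least 2 subjects")
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), np.broadcast_to(col_mean, X.shape), X)
    f = X.mean(axis=0) / 2.0
    poly = (f > 0) & (f < 1) & (X.var(axis=0) > 0)
    n_dropped = int((~poly).sum())
    if poly.sum() < 2:
        raise ValueError("fewer than 2 polymorphic SNPs; cannot run PCA")
    Xp = X[:, poly]
    fp = f[poly]
    Z = (Xp - 2 * fp) / np.sqrt(2 * fp * (1 - fp))
    cov = Z @ Z.T / Z.shape[1]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0, None)
    eigvecs = eigvecs[:, order]
    k = min(n_components, n_subj - 1)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    for j in range(k):  # deterministic sign: largest-|coordinate| entry positive
        i_max = np.argmax(np.abs(coords[:, j]))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    total = eigvals.sum()
    ratio = eigvals[:k] / total if total > 0 else np.zeros(k)
    df = pd.DataFrame(
        coords, index=genotypes.dosages.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    df.index.name = "subject_id"
    return PcaResult(coords=df, explained_variance_ratio=ratio, n_monomorphic_dropped=n_dropped)


def assign_ancestry(
    pcs: PcaResult | pd.DataFrame,
    self_report: pd.Series,
    k: int = 2,
    seed: int = 0,
    labels: tuple[str, str] = ("EA", "AA"),
) -> pd.Series:
    """Dichotomize subjects into genetic ancestry groups from the first two PCs.

    2-means clustering (k-means++ with a fixed seed) on PC1/PC2; each cluster
    is named by the majority self-reported ancestry of its members. If both
    clusters have the same majority, the cluster with the higher proportion of
    that label keeps it and the other receives the remaining label (ties break
    toward the larger cluster). Relabeling self-report wholesale flips the
    names but never the partition.
    """
    from sklearn.cluster import KMeans

    if k != 2:
        raise ValueError("only k=2 (EA/AA dichotomy) is supported")
    coords = pcs.coords if isinstance(pcs, PcaResult) else pcs
    X = coords.iloc[:, :2].to_numpy()
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    cluster = km.fit_predict(X)
    sizes = np.bincount(cluster, minlength=2)
    center_dist = float(np.linalg.norm(km.cluster_centers_[0] - km.cluster_centers_[1]))
    within = float(
        np.sqrt(np.mean(np.sum((X - km.cluster_centers_[cluster]) ** 2, axis=1)))
    )
    # one Gaussian blob split in half has center distance ~1.4x the within-cluster
    # RMS; genuinely separated populations sit well above 2
    if sizes.min() == 0 or center_dist < 2.0 * within:
        warnings.warn(
            "degenerate clustering: subjects do not form two separated groups",
            stacklevel=2,
        )
    sr = self_report.reindex(coords.index)
    lab_a, lab_b = labels
    prop_a = np.array(
        [np.mean(sr.to_numpy()[cluster == c] == lab_a) if sizes[c] else 0.0 for c in (0, 1)]
    )
    if prop_a[0] == prop_a[1]:
        # proportion tie: the larger cluster takes the overall-majority label
        majority = lab_a if (sr == lab_a).mean() >= 0.5 else lab_b
        big = int(np.argmax(sizes))
        mapping = {big: majority, 1 - big: lab_b if majority == lab_a else lab_a}
    else:
        a_cluster = int(np.argmax(prop_a))
        mapping = {a_cluster: lab_a, 1 - a_cluster: lab_b}
    out = pd.Series([mapping[c] for c in cluster], index=coords.index, name="genetic_ancestry")
    return out
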