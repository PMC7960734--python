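"""Synthetic multimodal cohorts with known ground truth.

The real study population (continued vs. remitted alcohol use disorder,
assessed at two visits) is restricted-access, so every downstream stage is
exercised on simulated cohorts instead. Generation is label-first: a balanced
remitted/continued label is drawn, then each modality is generated conditional
on it —

* ROI signals: per frequency band, band-limited Gaussian noise; a pair with a
  target band coherence shares a common band-limited source (see
  :func:`simulate_roi_signals` for the shared-component algebra).
* genetics: LD-blocked dosage genotypes from thresholded correlated Gaussians,
  GWAS summary statistics with planted causal effects, and an independent
  reference panel from the same LD process.
* demographics: binary covariates with configurable odds ratios of remission
  and a shared age distribution.

All randomness flows from one master seed, namespaced per modality so each
modality can be regenerated independently; identical (truth, seed) inputs
reproduce the cohort bit for bit.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfft, rfftfreq
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

from .eeg_connectivity import (
    DEFAULT_BANDS,
    BandDefinition,
    RoiTimeSeriesSet,
    load_roi_names,
)
from .genetics import GenotypeMatrix, SummaryStatsTable

__all__ = [
    "CoherenceEffect",
    "CausalSnp",
    "CohortTruth",
    "SubjectRecord",
    "SyntheticCohort",
    "MEDICATION_NAMES",
    "DEFAULT_COVARIATE_BASE_RATES",
    "generate_cohort",
    "simulate_roi_signals",
    "simulate_genetics",
    "simulate_demographics",
]

LABELS = ("continued", "remitted")

MEDICATION_NAMES = (
    "med_sleep",
    "med_anxiety",
    "med_headaches",
    "med_birth_control",
    "med_depression",
    "med_energy",
    "med_steroids",
    "med_other",
)

#: Base probabilities (in the continued-AUD group) for each binary covariate.
DEFAULT_COVARIATE_BASE_RATES: dict[str, float] = {
    "married": 0.45,
    "employed": 0.60,
    **{m: 0.10 for m in MEDICATION_NAMES},
}


@dataclasses.dataclass(frozen=True)
class CoherenceEffect:
    """A planted group difference in band coherence for one ROI pair."""

    roi_i: int
    roi_j: int
    band: str
    coherence_continued: float
    coherence_remitted: float

    def __post_init__(self) -> None:
        for v in (self.coherence_continued, self.coherence_remitted):
            if not (0.0 <= v <= 1.0):
                raise ValueError(
                    f"coherence target for pair ({self.roi_i}, {self.roi_j}) in band "
                    f"{self.band!r} outside [0, 1]: {v}"
                )
        if self.roi_i == self.roi_j:
            raise ValueError(f"coherence effect needs two distinct ROIs, got {self.roi_i} twice")

    def target(self, label: str) -> float:
        return self.coherence_remitted if label == "remitted" else self.coherence_continued


@dataclasses.dataclass(frozen=True)
class CausalSnp:
    """A SNP whose effect-allele dosage shifts the log-odds of remission."""

    snp_id: str
    effect_allele: str
    log_odds: float


@dataclasses.dataclass
class CohortTruth:
    """Complete ground-truth configuration for one synthetic cohort."""

    n_per_group: int
    coherence_effects: Sequence[CoherenceEffect] = ()
    causal_snps: Sequence[CausalSnp] = ()
    covariate_effects: Mapping[str, float] = dataclasses.field(default_factory=dict)
    baseline_log_odds: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        self.coherence_effects = tuple(
            e if isinstance(e, CoherenceEffect) else CoherenceEffect(*e)
            for e in self.coherence_effects
        )
        self.causal_snps = tuple(
            c if isinstance(c, CausalSnp) else CausalSnp(*c) for c in self.causal_snps
        )
        unknown = set(self.covariate_effects) - set(DEFAULT_COVARIATE_BASE_RATES)
        if unknown:
            raise ValueError(f"unknown covariates in covariate_effects: {sorted(unknown)}")


@dataclasses.dataclass
class SubjectRecord:
    """Phenotype/demographic record for one subject (visit-1 data, visit-2 label)."""

    subject_id: str
    sex: str  # male | female
    self_report_ancestry: str  # EA | AA
    age_visit1: float
    label: str  # continued | remitted
    marital_status: str  # married | not married
    employment_status: str  # employed | not employed
    medications: dict[str, int] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    signals: RoiTimeSeriesSet
    genotypes: GenotypeMatrix
    summary_stats: SummaryStatsTable
    reference_panel: GenotypeMatrix
    truth: CohortTruth

    @property
    def labels(self) -> pd.Series:
        return pd.Series(
            {s.subject_id: s.label for s in self.subjects}, name="label"
        ).loc[[s.subject_id for s in self.subjects]]


def _modality_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent, reproducible stream per modality from one master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _band_limited_noise(
    rng: np.random.Generator, n_samples: int, fs: float, band: BandDefinition, size: int = 1
) -> np.ndarray:
    """Unit-variance Gaussian noise whose spectrum is confined to [low, high).

    Brick-wall filtering in the frequency domain gives every draw an identical
    flat in-band spectral shape, which the shared-component coherence algebra
    below relies on.
    """
    white = rng.standard_normal((size, n_samples))
    spec = rfft(white, axis=-1)
    freqs = rfftfreq(n_samples, d=1.0 / fs)
    spec[:, ~band.mask(freqs)] = 0.0
    x = irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_roi_signals(
    labels: Mapping[str, str],
    coherence_effects: Sequence[CoherenceEffect],
    n_rois: int = 68,
    fs: float = 256.0,
    duration: float = 240.0,
    seed: int = 0,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    roi_names: Sequence[str] | None = None,
) -> RoiTimeSeriesSet:
    """Simulate per-subject ROI signals with planted band-coherence structure.

    Each ROI signal is a sum of independent band-limited noise components, one
    per band. For a pair (i, j) with target magnitude-squared coherence gamma2
    in band b, the band-b components are built from a shared source s and
    independent noises e1, e2 (all unit-variance with identical in-band
    spectra):

        x = a*s + sqrt(1 - a^2)*e1,   y = a*s + sqrt(1 - a^2)*e2.

    At any in-band frequency the cross-spectrum is S_xy = a^2 * P and both
    auto-spectra equal a^2*P + (1-a^2)*P = P, so

        MSC = |S_xy|^2 / (S_xx * S_yy) = (a^2 * P)^2 / P^2 = a^4,

    and the mixing weight that realizes a target gamma2 is a = gamma2 ** (1/4)
    (equivalently a = sqrt(gamma) with gamma the magnitude coherence). Targets
    may differ between the continued and remitted groups; unplanted pairs
    receive independent noise in every band (coherence at the estimator's bias
    floor only).
    """
    n_samples = int(round(duration * fs))
    min_duration = 2.0  # one default Welch segment
    if duration < min_duration:
        raise ValueError(
            f"duration {duration} s too short: at least {min_duration} s "
            "(one spectral segment) is required"
        )
    if n_rois < 2:
        raise ValueError("n_rois must be >= 2")
    band_by_name = {b.name: b for b in bands}
    seen: set[tuple[int, int, str]] = set()
    for eff in coherence_effects:
        if not (0 <= eff.roi_i < n_rois and 0 <= eff.roi_j < n_rois):
            raise ValueError(f"effect pair ({eff.roi_i}, {eff.roi_j}) outside 0..{n_rois - 1}")
        if eff.band not in band_by_name:
            raise ValueError(f"unknown band {eff.band!r}")
        for roi in (eff.roi_i, eff.roi_j):
            key = (roi, eff.band)
            if key in seen:
                raise ValueError(
                    f"ROI {roi} participates in two effects in band {eff.band!r}; "
                    "one shared source per (ROI, band) is supported"
                )
            seen.add(key)

    if roi_names is None:
        roi_names = load_roi_names()[:n_rois] if n_rois <= 68 else [
            f"roi{i:03d}" for i in range(n_rois)
        ]
    roi_names = list(roi_names)
    if len(roi_names) != n_rois:
        raise ValueError("roi_names length must equal n_rois")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    effects_by_band: dict[str, list[CoherenceEffect]] = {}
    for eff in coherence_effects:
        effects_by_band.setdefault(eff.band, []).append(eff)

    data: dict[str, np.ndarray] = {}
    for sid in labels:
        label = labels[sid]
        sig = np.zeros((n_rois, n_samples))
        for band in bands:
            comp = _band_limited_noise(rng, n_samples, fs, band, size=n_rois)
            for eff in effects_by_band.get(band.name, []):
                gamma2 = eff.target(label)
                a = gamma2 ** 0.25
                shared_and_noise = _band_limited_noise(rng, n_samples, fs, band, size=3)
                s, e1, e2 = shared_and_noise
                comp[eff.roi_i] = a * s + np.sqrt(1 - a * a) * e1
                comp[eff.roi_j] = a * s + np.sqrt(1 - a * a) * e2
            sig += comp
        data[sid] = sig
    return RoiTimeSeriesSet(
        subject_ids=list(labels), data=data, fs=fs, roi_names=roi_names
    )


def _latent_corr_for_allele_corr(target_r: float, f: float) -> float:
    """Latent Gaussian correlation giving binary-allele correlation target_r.

    An allele indicator is 1{z < Phi^-1(f)}; for two standard normals with
    correlation c the indicator correlation is
    (Phi2(t, t; c) - f^2) / (f (1 - f)). Inverted numerically.
    """
    if target_r <= 0:
        return 0.0
    if target_r >= 1:
        return 1.0
    t = norm.ppf(f)

    def gap(c: float) -> float:
        p11 = multivariate_normal(mean=[0, 0], cov=[[1, c], [c, 1]]).cdf([t, t])
        return (p11 - f * f) / (f * (1 - f)) - target_r

    return float(brentq(gap, 0.0, 1.0 - 1e-9, xtol=1e-10))


def _draw_block_dosages(
    rng: np.random.Generator, n_subjects: int, n_snps: int, latent_c: float, f: float
) -> np.ndarray:
    """Dosages {0,1,2} for one LD block: two haplotypes of correlated indicators."""
    t = norm.ppf(f)
    dosage = np.zeros((n_subjects, n_snps), dtype=float)
    for _hap in range(2):
        shared = rng.standard_normal((n_subjects, 1))
        noise = rng.standard_normal((n_subjects, n_snps))
        z = np.sqrt(latent_c) * shared + np.sqrt(1 - latent_c) * noise
        dosage += (z < t).astype(float)
    return dosage


def simulate_genetics(
    labels: Mapping[str, str],
    causal_snps: Sequence[CausalSnp],
    n_snps: int = 200,
    n_blocks: int = 20,
    block_r2: float = 0.5,
    seed: int = 0,
    baseline_log_odds: float = 0.0,
    n_reference: int = 200,
    maf_range: tuple[float, float] = (0.1, 0.5),
    allele_freqs: Sequence[float] | None = None,
) -> tuple[GenotypeMatrix, SummaryStatsTable, GenotypeMatrix]:
    """Simulate LD-blocked genotypes, GWAS summary statistics and a reference panel.

    SNPs are laid out in ``n_blocks`` contiguous blocks on one chromosome;
    within a block, dosages come from thresholded equicorrelated Gaussians
    tuned so that pairwise dosage r² is approximately ``block_r2`` (blocks
    share one allele frequency, drawn uniformly from ``maf_range``, so the
    target is attainable); across blocks r² is ~0. Blocks span < 500 kb and
    are separated by 1 Mb. Causal SNPs (one per block, in block order) shift
    the log-odds of the remitted label per dosage unit; label-conditional
    genotypes are drawn by rejection sampling against the logistic model so
    the LD structure is preserved. The reference panel is an independent draw
    from the same LD process.
    """
    causal_snps = tuple(c if isinstance(c, CausalSnp) else CausalSnp(*c) for c in causal_snps)
    if n_snps < len(causal_snps):
        raise ValueError("n_snps must be >= number of causal SNPs")
    if n_blocks < 1 or n_snps < n_blocks:
        raise ValueError("need 1 <= n_blocks <= n_snps")
    if not (0.0 <= block_r2 <= 1.0):
        raise ValueError("block_r2 must be in [0, 1]")
    if len(causal_snps) > n_blocks:
        raise ValueError("at most one causal SNP per block is supported")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))

    sizes = np.full(n_blocks, n_snps // n_blocks, dtype=int)
    sizes[: n_snps % n_blocks] += 1
    if allele_freqs is None:
        block_freqs = rng.uniform(*maf_range, size=n_blocks)
        freqs = np.repeat(block_freqs, sizes)
    else:
        freqs = np.asarray(allele_freqs, dtype=float)
        if len(freqs) != n_snps:
            raise ValueError("allele_freqs must have length n_snps")
        if block_r2 == 1.0:
            start = 0
            for m in sizes:
                if np.unique(freqs[start : start + m]).size > 1:
                    raise ValueError(
                        "block_r2 = 1 requires identical allele frequencies within a block"
                    )
                start += m

    # SNP metadata: ids, positions (blocks < 500 kb wide, 1 Mb apart), alleles.
    snp_ids = [f"snp{i + 1:05d}" for i in range(n_snps)]
    causal_cols: dict[int, CausalSnp] = {}
    start = 0
    starts = []
    for b, m in enumerate(sizes):
        starts.append(start)
        if b < len(causal_snps):
            causal_cols[start] = causal_snps[b]
            snp_ids[start] = causal_snps[b].snp_id
        start += m
    pos = np.empty(n_snps, dtype=int)
    for b, (st, m) in enumerate(zip(starts, sizes)):
        pos[st : st + m] = 1 + b * 1_000_000 + np.arange(m) * 1_000
    a1 = np.full(n_snps, "A", dtype=object)
    a2 = np.full(n_snps, "G", dtype=object)
    for col, cs in causal_cols.items():
        a1[col] = cs.effect_allele
        a2[col] = "G" if cs.effect_allele != "G" else "A"

    target_r = np.sqrt(block_r2)
    latent_by_block = []
    f_by_block = []
    st = 0
    for m in sizes:
        f = float(freqs[st])
        f_by_block.append(f)
        latent_by_block.append(_latent_corr_for_allele_corr(target_r, f))
        st += m

    def draw_cohort(n: int, gen: np.random.Generator) -> np.ndarray:
        cols = []
        for m, c, f in zip(sizes, latent_by_block, f_by_block):
            cols.append(_draw_block_dosages(gen, n, m, c, f))
        return np.concatenate(cols, axis=1)

    # Label-conditional genotypes by rejection: accept a draw with probability
    # P(label | dosages) from the logistic model, preserving LD exactly.
    effect_vec = np.zeros(n_snps)
    for col, cs in causal_cols.items():
        effect_vec[col] = cs.log_odds
    subject_ids = list(labels)
    geno = np.empty((len(subject_ids), n_snps))
    max_tries = 2000
    for i, sid in enumerate(subject_ids):
        want_remitted = labels[sid] == "remitted"
        for _try in range(max_tries):
            g = draw_cohort(1, rng)[0]
            eta = baseline_log_odds + g @ effect_vec
            p_rem = 1.0 / (1.0 + np.exp(-eta))
            accept_p = p_rem if want_remitted else 1.0 - p_rem
            if rng.uniform() < accept_p:
                geno[i] = g
                break
        else:
            raise RuntimeError(
                f"rejection sampling failed for subject {sid}; effects too extreme"
            )

    ref = draw_cohort(n_reference, rng)

    # Summary statistics: planted small p / stated sign for causal SNPs,
    # null beta and uniform p elsewhere.
    beta = rng.normal(0.0, 0.05, size=n_snps)
    pvals = rng.uniform(1e-4, 1.0, size=n_snps)
    for col, cs in causal_cols.items():
        beta[col] = cs.log_odds
        pvals[col] = 10.0 ** rng.uniform(-10, -6)
    stats = SummaryStatsTable(
        pd.DataFrame(
            {
                "snp": snp_ids,
                "chr": "1",
                "pos": pos,
                "a1": a1,
                "a2": a2,
                "beta": beta,
                "p": pvals,
            }
        )
    )
    snp_info = stats.table.set_index("snp")[["chr", "pos", "a1", "a2"]]
    genotypes = GenotypeMatrix(
        pd.DataFrame(geno, index=pd.Index(subject_ids, name="subject_id"), columns=snp_ids),
        snp_info,
    )
    reference = GenotypeMatrix(
        pd.DataFrame(
            ref,
            index=pd.Index([f"ref{i + 1:04d}" for i in range(n_reference)], name="subject_id"),
            columns=snp_ids,
        ),
        snp_info,
    )
    return genotypes, stats, reference


def simulate_demographics(
    labels: Mapping[str, str],
    covariate_effects: Mapping[str, float],
    seed: int = 0,
    base_rates: Mapping[str, float] | None = None,
    age_mean: float = 30.7,
    age_sd: float = 9.4,
    p_male: float = 0.6,
    p_ea: float = 0.6,
) -> list[SubjectRecord]:
    """Draw demographic / medication covariates conditional on outcome label.

    Each binary covariate has a base probability p0 in the continued group;
    the remitted group's odds are multiplied by exp(log-odds) from
    ``covariate_effects`` (absent covariates have odds ratio 1). Ages come
    from one normal distribution (mean 30.7, sd 9.4 years, truncated at 18)
    shared by both groups; sex and self-reported ancestry are label-independent.
    """
    rates = dict(DEFAULT_COVARIATE_BASE_RATES if base_rates is None else base_rates)
    for name, lo in covariate_effects.items():
        p0 = rates[name]
        odds = p0 / (1 - p0) * np.exp(lo)
        p1 = odds / (1 + odds)
        if not (0 < p1 < 1):
            raise ValueError(f"covariate {name!r}: implied remitted-group probability {p1}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    records = []
    for sid, label in labels.items():
        probs = {}
        for name, p0 in rates.items():
            lo = covariate_effects.get(name, 0.0)
            if label == "remitted" and lo != 0.0:
                odds = p0 / (1 - p0) * np.exp(lo)
                probs[name] = odds / (1 + odds)
            else:
                probs[name] = p0
        draws = {name: int(rng.uniform() < p) for name, p in probs.items()}
        age = age_mean + age_sd * rng.standard_normal()
        while age < 18.0:  # truncate: adult cohort
            age = age_mean + age_sd * rng.standard_normal()
        records.append(
            SubjectRecord(
                subject_id=sid,
                sex="male" if rng.uniform() < p_male else "female",
                self_report_ancestry="EA" if rng.uniform() < p_ea else "AA",
                age_visit1=float(age),
                label=label,
                marital_status="married" if draws["married"] else "not married",
                employment_status="employed" if draws["employed"] else "not employed",
                medications={m: draws[m] for m in MEDICATION_NAMES},
            )
        )
    return records


def generate_cohort(
    truth: CohortTruth,
    n_rois: int = 68,
    fs: float = 256.0,
    duration: float = 240.0,
    n_snps: int = 200,
    n_blocks: int = 20,
    block_r2: float = 0.5,
    n_reference: int = 200,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    roi_names: Sequence[str] | None = None,
) -> SyntheticCohort:
    """Generate a complete balanced synthetic cohort from a truth configuration.

    The outcome label is assigned first (n_per_group subjects per group, order
    shuffled deterministically from the master seed); signals, genetics and
    demographics are then drawn conditional on it via independent per-modality
    random streams. The truth object is embedded in the returned cohort.
    """
    label_rng = _modality_rng(truth.seed, 0)
    n = truth.n_per_group
    label_vec = np.array(["continued"] * n + ["remitted"] * n)
    label_rng.shuffle(label_vec)
    width = max(4, len(str(2 * n)))
    labels = {f"S{i + 1:0{width}d}": lab for i, lab in enumerate(label_vec)}

    signals = simulate_roi_signals(
        labels,
        truth.coherence_effects,
        n_rois=n_rois,
        fs=fs,
        duration=duration,
        seed=int(_modality_rng(truth.seed, 1).integers(2**31)),
        bands=bands,
        roi_names=roi_names,
    )
    genotypes, stats, reference = simulate_genetics(
        labels,
        truth.causal_snps,
        n_snps=n_snps,
        n_blocks=n_blocks,
        block_r2=block_r2,
        seed=int(_modality_rng(truth.seed, 2).integers(2**31)),
        baseline_log_odds=truth.baseline_log_odds,
        n_reference=n_reference,
    )
    subjects = simulate_demographics(
        labels,
        truth.covariate_effects,
        seed=int(_modality_rng(truth.seed, 3).integers(2**31)),
    )
    return SyntheticCohort(
        subjects=subjects,
        signals=signals,
        genotypes=genotypes,
        summary_stats=stats,
        reference_panel=reference,
        truth=truth,
    )
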