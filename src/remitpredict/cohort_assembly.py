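"""Assemble modality feature blocks into labeled, stratified, matched tables.

The analysis design stratifies the cohort by sex and ancestry (self-reported
or genetically assigned), age-matches the remitted and continued groups within
each stratum, drops subjects with missing values for the chosen feature set
(listwise deletion), and Z-normalizes features. Normalization supports a
fit/transform split so cross-validation can apply training-fold statistics to
held-out rows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import MEDICATION_NAMES, SubjectRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "StratumSpec",
    "MODALITIES",
    "build_feature_table",
    "stratify",
    "age_match",
    "complete_cases",
    "znormalize",
]

MODALITIES = ("EEG", "PRS", "demographic", "medication")

_META_COLUMNS = ("label", "sex", "self_report_ancestry", "age_visit1")


@dataclasses.dataclass
class FeatureTable:
    """Subjects x named features with modality tags, labels and stratum metadata.

    ``features``: numeric DataFrame (NaN = missing); ``tags``: feature name ->
    modality; ``meta``: per-subject label, sex, self-reported ancestry, age
    (and optionally a genetic-ancestry column).
    """

    features: pd.DataFrame
    tags: dict[str, str]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.features.columns.duplicated().any():
            dups = list(self.features.columns[self.features.columns.duplicated()])
            raise ValueError(f"duplicate feature names: {dups[:5]}")
        untagged = set(self.features.columns) - set(self.tags)
        if untagged:
            raise ValueError(f"untagged features: {sorted(untagged)[:5]}")
        if not self.features.index.equals(self.meta.index):
            raise ValueError("features and meta must share the subject index")
        if self.features.index.duplicated().any():
            raise ValueError("duplicate subject ids")

    @property
    def labels(self) -> pd.Series:
        return self.meta["label"]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.features.index)

    def select(self, subjects=None, columns=None) -> "FeatureTable":
        feats = self.features
        meta = self.meta
        if subjects is not None:
            feats = feats.loc[subjects]
            meta = meta.loc[subjects]
        if columns is not None:
            feats = feats[list(columns)]
        tags = {c: self.tags[c] for c in feats.columns}
        return FeatureTable(feats, tags, meta)

    def write_csv(self, path) -> None:
        """Single-CSV round-trip format: metadata columns first, then features."""
        out = pd.concat([self.meta, self.features], axis=1)
        out.to_csv(path, index_label="subject_id")
        with open(str(path) + ".tags.json", "w") as fh:
            json.dump(self.tags, fh, indent=0, sort_keys=True)

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="subject_id")
        with open(str(path) + ".tags.json") as fh:
            tags = json.load(fh)
        meta_cols = [c for c in df.columns if c not in tags]
        return cls(df[[c for c in df.columns if c in tags]], tags, df[meta_cols])


@dataclasses.dataclass
class StratumSpec:
    """One analysis stratum: sex x ancestry, and the feature subset to model."""

    sex: str  # male | female
    ancestry: str  # EA | AA
    ancestry_mode: str = "self_report"  # self_report | genetic
    selector: Sequence[str] = MODALITIES  # modality tags and/or feature names

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.ancestry_mode not in ("self_report", "genetic"):
            raise ValueError(f"ancestry_mode must be self_report/genetic")
        if len(self.selector) == 0:
            raise ValueError("feature selector is empty")

    @property
    def name(self) -> str:
        return f"{self.ancestry}_{self.sex}_{self.ancestry_mode}"


def _demographic_block(phenotypes: Sequence[SubjectRecord]) -> tuple[pd.DataFrame, dict[str, str]]:
    rows = {}
    for rec in phenotypes:
        rows[rec.subject_id] = {
            "married": 1.0 if rec.marital_status == "married" else 0.0,
            "employed": 1.0 if rec.employment_status == "employed" else 0.0,
            **{m: float(rec.medications.get(m, 0)) for m in MEDICATION_NAMES},
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    tags = {"married": "demographic", "employed": "demographic"}
    tags.update({m: "medication" for m in MEDICATION_NAMES})
    return df, tags


def build_feature_table(
    blocks: Sequence[tuple[str, pd.DataFrame]],
    phenotypes: Sequence[SubjectRecord],
) -> FeatureTable:
    """Outer-join modality blocks on subject id and attach phenotype metadata.

    ``blocks`` are (modality tag, subjects x features) pairs, e.g.
    ("EEG", coherence features) and ("PRS", score matrix). Marital/employment
    status and the eight medication flags are encoded from the phenotype
    records as binary indicator features. Subjects present in one block but
    not another get missing values there (listwise deletion happens later, per
    model feature set). Duplicate feature names across blocks are an error.
    """
    demo, tags = _demographic_block(phenotypes)
    all_blocks = list(blocks) + [("demographic+medication", demo)]
    seen: dict[str, str] = {}
    collisions = []
    for name, df in all_blocks:
        for col in df.columns:
            if col in seen:
                collisions.append(col)
            seen[col] = name
    if collisions:
        raise ValueError(f"duplicate feature names across blocks: {sorted(set(collisions))[:10]}")

    for modality, df in blocks:
        if modality not in ("EEG", "PRS", "demographic", "medication"):
            raise ValueError(f"unknown modality tag {modality!r}")
        tags.update({c: modality for c in df.columns})

    features = pd.concat([df for _, df in all_blocks], axis=1, join="outer")
    meta = pd.DataFrame.from_dict(
        {
            rec.subject_id: {
                "label": rec.label,
                "sex": rec.sex,
                "self_report_ancestry": rec.self_report_ancestry,
                "age_visit1": rec.age_visit1,
            }
            for rec in phenotypes
        },
        orient="index",
    )
    features = features.reindex(features.index.union(meta.index, sort=True))
    meta = meta.reindex(features.index)
    features.index.name = "subject_id"
    meta.index.name = "subject_id"
    return FeatureTable(features, tags, meta)


def _resolve_selector(table: FeatureTable, selector: Sequence[str]) -> list[str]:
    cols = []
    for item in selector:
        if item in MODALITIES:
            cols.extend([c for c, t in table.tags.items() if t == item])
        elif item in table.features.columns:
            cols.append(item)
        else:
            raise KeyError(f"selector item {item!r} is neither a modality tag nor a feature")
    # preserve table column order, drop duplicates
    colset = set(cols)
    return [c for c in table.features.columns if c in colset]


def stratify(
    table: FeatureTable,
    spec: StratumSpec,
    genetic_ancestry: pd.Series | Mapping[str, str] | None = None,
) -> FeatureTable:
    """Restrict to one sex x ancestry stratum and the selected feature columns."""
    if spec.ancestry_mode == "genetic":
        if genetic_ancestry is None:
            raise ValueError("ancestry_mode='genetic' requires a genetic ancestry assignment")
        anc = pd.Series(genetic_ancestry).reindex(table.features.index)
    else:
        anc = table.meta["self_report_ancestry"]
    mask = (table.meta["sex"] == spec.sex) & (anc == spec.ancestry)
    if not mask.any():
        counts = (
            pd.DataFrame({"sex": table.meta["sex"], "ancestry": anc})
            .value_counts()
            .to_dict()
        )
        raise ValueError(
            f"empty stratum ({spec.sex}, {spec.ancestry}, {spec.ancestry_mode}); "
            f"available strata: {counts}"
        )
    cols = _resolve_selector(table, spec.selector)
    out = table.select(subjects=table.features.index[mask], columns=cols)
    logger.info("stratum %s: %d subjects, %d features", spec.name, len(out.features), len(cols))
    return out


def age_match(
    table: FeatureTable,
    caliper: float = 2.0,
    group_col: str = "label",
    groups: tuple[str, str] = ("continued", "remitted"),
) -> tuple[FeatureTable, list[tuple[str, str]]]:
    """Greedy 1:1 nearest-neighbor age matching across the two outcome groups.

    Candidate cross-group pairs are taken in order of (|age difference|,
    subject id A, subject id B); each subject is used at most once and pairs
    exceeding the caliper are dropped, giving equal-sized matched groups whose
    mean ages differ by at most the caliper.
    """
    meta = table.meta
    a_ids = meta.index[meta[group_col] == groups[0]]
    b_ids = meta.index[meta[group_col] == groups[1]]
    if len(a_ids) == 0 or len(b_ids) == 0:
        raise ValueError("both outcome groups must be non-empty for age matching")
    ages_a = meta.loc[a_ids, "age_visit1"]
    ages_b = meta.loc[b_ids, "age_visit1"]
    candidates = sorted(
        (
            (abs(ages_a[ia] - ages_b[ib]), ia, ib)
            for ia in a_ids
            for ib in b_ids
        ),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for diff, ia, ib in candidates:
        if diff > caliper:
            break
        if ia in used_a or ib in used_b:
            continue
        pairs.append((ia, ib))
        used_a.add(ia)
        used_b.add(ib)
    if not pairs:
        raise ValueError(f"no age pairs within caliper {caliper} years")
    keep = [i for pair in pairs for i in pair]
    keep = [i for i in table.features.index if i in set(keep)]
    logger.info(
        "age matching: %d pairs, %d subjects dropped", len(pairs), len(table.features) - 2 * len(pairs)
    )
    return table.select(subjects=keep), pairs


def complete_cases(table: FeatureTable) -> FeatureTable:
    """Listwise deletion: drop subjects missing any selected feature or label."""
    missing_label = table.meta["label"].isna()
    missing_any = table.features.isna().any(axis=1) | missing_label
    if missing_any.all():
        raise ValueError("all subjects have missing values in the selected feature set")
    if missing_any.any():
        by_modality = {
            m: int(
                table.features[[c for c, t in table.tags.items() if t == m]]
                .isna()
                .any(axis=1)
                .sum()
            )
            for m in set(table.tags.values())
        }
        logger.info(
            "complete cases: dropping %d/%d subjects (missingness by modality: %s)",
            int(missing_any.sum()),
            len(table.features),
            by_modality,
        )
    return table.select(subjects=table.features.index[~missing_any])


def znormalize(
    table: FeatureTable,
    statistics: pd.DataFrame | None = None,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Z-score features; fit-and-transform, or transform-only with given statistics.

    Passing the statistics frame returned by a previous call applies those
    means/sds without refitting — the leakage-free way to normalize held-out
    rows with training-fold statistics. Constant features are zeroed with a
    warning when fitting.
    """
    if statistics is None:
        if len(table.features) < 2:
            raise ValueError("need >= 2 rows to fit normalization statistics")
        mean = table.features.mean(axis=0)
        sd = table.features.std(axis=0, ddof=1)
        const = sd == 0
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant feature(s) zeroed during Z-normalization",
                stacklevel=2,
            )
        statistics = pd.DataFrame({"mean": mean, "sd": sd.where(~const, 1.0), "constant": const})
    stats = statistics.reindex(table.features.columns)
    z = (table.features - stats["mean"]) / stats["sd"]
    if stats["constant"].any():
        z.loc[:, stats.index[stats["constant"].astype(bool)]] = 0.0
    return FeatureTable(z, dict(table.tags), table.meta.copy()), statistics
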