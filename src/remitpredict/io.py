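"""Readers and writers for the pipeline's on-disk formats.

ROI signals travel as HDF5 (one dataset per subject, with sampling rate and
ROI names as attributes) with a per-subject CSV fallback; genotypes as a
dosage TSV plus a plain-text VCF (dosages derived from GT on read); summary
statistics as a TSV with header ``snp chr pos a1 a2 beta p``; phenotypes as a
CSV; ground truth as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .eeg_connectivity import RoiTimeSeriesSet
from .genetics import GenotypeMatrix
from .synthetic_cohort import (
    MEDICATION_NAMES,
    CohortTruth,
    SubjectRecord,
    SyntheticCohort,
)

__all__ = [
    "write_signals_hdf5",
    "read_signals_hdf5",
    "write_signals_csv",
    "read_signals_csv",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
    "write_vcf",
    "read_vcf",
    "write_truth_json",
    "write_cohort",
]


def write_signals_hdf5(ts_set: RoiTimeSeriesSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = ts_set.fs
        f.attrs["roi_names"] = [n.encode() for n in ts_set.roi_names]
        for sid in ts_set.subject_ids:
            f.create_dataset(sid, data=ts_set.data[sid], compression="gzip")


def read_signals_hdf5(path) -> RoiTimeSeriesSet:
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])
        roi_names = [n.decode() if isinstance(n, bytes) else str(n) for n in f.attrs["roi_names"]]
        subject_ids = sorted(f.keys())
        data = {sid: f[sid][()] for sid in subject_ids}
    return RoiTimeSeriesSet(subject_ids=subject_ids, data=data, fs=fs, roi_names=roi_names)


def write_signals_csv(ts_set: RoiTimeSeriesSet, directory) -> None:
    """CSV fallback: one ``<subject>.csv`` per subject (ROI rows), plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid in ts_set.subject_ids:
        pd.DataFrame(ts_set.data[sid], index=ts_set.roi_names).to_csv(
            directory / f"{sid}.csv", header=False
        )
    with open(directory / "manifest.json", "w") as fh:
        json.dump({"fs": ts_set.fs, "roi_names": ts_set.roi_names,
                   "subjects": list(ts_set.subject_ids)}, fh, indent=1)


def read_signals_csv(directory) -> RoiTimeSeriesSet:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    data = {
        sid: pd.read_csv(directory / f"{sid}.csv", header=None, index_col=0).to_numpy(dtype=float)
        for sid in manifest["subjects"]
    }
    return RoiTimeSeriesSet(
        subject_ids=manifest["subjects"], data=data,
        fs=manifest["fs"], roi_names=manifest["roi_names"],
    )


def write_coherence_hdf5(block, path) -> None:
    """Per-band coherence matrices: one ``<subject>/<band>`` dataset each."""
    with h5py.File(path, "w") as f:
        f.attrs["roi_names"] = [n.encode() for n in block.roi_names]
        f.attrs["bands"] = [b.encode() for b in block.band_names]
        for sid, by_band in block.matrices.items():
            grp = f.create_group(sid)
            for band, mat in by_band.items():
                grp.create_dataset(band, data=mat, compression="gzip")


def read_coherence_hdf5(path) -> dict[str, dict[str, np.ndarray]]:
    with h5py.File(path, "r") as f:
        return {
            sid: {band: f[sid][band][()] for band in f[sid]} for sid in f.keys()
        }


def write_phenotypes_csv(subjects: list[SubjectRecord], path) -> None:
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "sex": s.sex,
            "self_report_ancestry": s.self_report_ancestry,
            "age_visit1": s.age_visit1,
            "label": s.label,
            "marital_status": s.marital_status,
            "employment_status": s.employment_status,
        }
        row.update({m: s.medications.get(m, 0) for m in MEDICATION_NAMES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_phenotypes_csv(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        SubjectRecord(
            subject_id=str(r["subject_id"]),
            sex=r["sex"],
            self_report_ancestry=r["self_report_ancestry"],
            age_visit1=float(r["age_visit1"]),
            label=r["label"],
            marital_status=r["marital_status"],
            employment_status=r["employment_status"],
            medications={m: int(r[m]) for m in MEDICATION_NAMES},
        )
        for _, r in df.iterrows()
    ]


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Plain-text VCFv4.2 with hard GT calls from integer dosages.

    Fractional or missing dosages are written as ``./.``; the dosage TSV is
    the lossless interchange format.
    """
    subjects = genotypes.subject_ids
    info = genotypes.snp_info
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(subjects) + "\n")
        for snp in genotypes.snp_ids:
            meta = info.loc[snp]
            # REF = other allele, ALT = effect allele, so ALT count == dosage
            calls = []
            for d in genotypes.dosages[snp]:
                if pd.isna(d) or float(d) != int(d):
                    calls.append("./.")
                else:
                    calls.append(gt_map[int(d)])
            fh.write(
                f"{meta['chr']}\t{int(meta['pos'])}\t{snp}\t{meta['a2']}\t{meta['a1']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into an effect-allele (ALT) dosage matrix via cyvcf2."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    ids, chrs, poss, refs, alts, rows = [], [], [], [], [], []
    for var in vcf:
        ids.append(var.ID)
        chrs.append(str(var.CHROM))
        poss.append(int(var.POS))
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = np.array(var.gt_types, dtype=float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
    dosages = pd.DataFrame(
        np.array(rows).T, index=pd.Index(subjects, name="subject_id"), columns=ids
    )
    snp_info = pd.DataFrame(
        {"chr": chrs, "pos": poss, "a1": alts, "a2": refs}, index=pd.Index(ids, name="snp")
    )
    return GenotypeMatrix(dosages, snp_info)


def write_truth_json(truth: CohortTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=1, default=list)


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, str]:
    """Write every cohort component under ``directory``; returns name -> path."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": d / "phenotypes.csv",
        "signals_h5": d / "roi_signals.h5",
        "dosages": d / "genotypes.dosage.tsv",
        "snp_info": d / "genotypes.snps.tsv",
        "vcf": d / "genotypes.vcf",
        "reference_dosages": d / "reference.dosage.tsv",
        "sumstats": d / "summary_stats.tsv",
        "truth": d / "truth.json",
    }
    write_phenotypes_csv(cohort.subjects, paths["phenotypes"])
    write_signals_hdf5(cohort.signals, paths["signals_h5"])
    cohort.genotypes.to_tsv(paths["dosages"], paths["snp_info"])
    write_vcf(cohort.genotypes, paths["vcf"])
    cohort.reference_panel.to_tsv(paths["reference_dosages"])
    cohort.summary_stats.to_tsv(paths["sumstats"])
    write_truth_json(cohort.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
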