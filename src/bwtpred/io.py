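"""Tabular readers/writers for the pipeline exchange formats.

All files are tab-delimited UTF-8 with '.' decimal separators.  Genomic
coordinates are 1-based and end-inclusive throughout, including the
BED-like CNV segment tables.  Missing tumor purity is encoded as an empty
field (never 0, which is a legal purity).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

TISSUES = frozenset({"blood", "kidney", "tumor"})
LATERALITIES = frozenset({"left", "right", "unknown"})

SAMPLE_SHEET_COLUMNS = ["sample_id", "patient_id", "tissue", "laterality", "purity", "cohort"]
CNV_COLUMNS = ["sample_id", "chrom", "start", "end", "value", "cnloh"]
GERMLINE_COLUMNS = [
    "patient_id", "gene", "variant_class", "protein_change", "clinvar",
    "provean", "polyphen", "germline_ref", "germline_alt", "tumor_ref", "tumor_alt",
]
SOMATIC_CODING_COLUMNS = ["sample_id", "gene", "protein_change"]
SOMATIC_NONCODING_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt"]


class ProbeBetaMatrix:
    """Probe-by-sample methylation beta values with genomic coordinates.

    Parameters
    ----------
    probes
        DataFrame indexed by probe id with columns ``chrom`` and ``pos``.
    beta
        DataFrame indexed by probe id (same index) with one column per
        sample id; values are beta fractions in [0, 1] (NaN = missing).
    """

    def __init__(self, probes: pd.DataFrame, beta: pd.DataFrame):
        if not probes.index.equals(beta.index):
            raise ValidationError("probe annotation and beta matrix indexes differ")
        if probes.index.has_duplicates:
            dups = probes.index[probes.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if probes.duplicated(subset=["chrom", "pos"]).any():
            raise ValidationError("duplicate (chrom, pos) across probe ids")
        vals = beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValidationError(
                f"beta value out of [0, 1] at probe {probes.index[i]!r}, "
                f"sample {beta.columns[j]!r}: {vals[i, j]}"
            )
        self.probes = probes[["chrom", "pos"]].copy()
        self.probes["pos"] = self.probes["pos"].astype(np.int64)
        self.beta = beta.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.probes.index

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def subset(self, probe_ids: Iterable[str]) -> "ProbeBetaMatrix":
        ids = pd.Index(probe_ids)
        return ProbeBetaMatrix(self.probes.loc[ids], self.beta.loc[ids])

    @classmethod
    def read(cls, path: str | Path) -> "ProbeBetaMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
        required = ["probe_id", "chrom", "pos"]
        if list(df.columns[:3]) != required:
            raise FormatError(
                f"{path}: header must start with {required}, got {list(df.columns[:3])}"
            )
        sample_cols = list(df.columns[3:])
        if not sample_cols:
            raise FormatError(f"{path}: no sample columns after probe_id/chrom/pos")
        df = df.set_index("probe_id")
        return cls(df[["chrom", "pos"]], df[sample_cols])

    def write(self, path: str | Path, decimals: int = 6) -> None:
        out = pd.concat([self.probes, self.beta.round(decimals)], axis=1)
        out.to_csv(path, sep="\t", index_label="probe_id", float_format=f"%.{decimals}f")


def read_beta_matrix(path: str | Path) -> ProbeBetaMatrix:
    return ProbeBetaMatrix.read(path)


def write_beta_matrix(matrix: ProbeBetaMatrix, path: str | Path) -> None:
    matrix.write(path)


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    df = df[SAMPLE_SHEET_COLUMNS].copy()
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in sample sheet")
    bad_tissue = set(df["tissue"]) - TISSUES
    if bad_tissue:
        raise ValidationError(f"unknown tissue values: {sorted(bad_tissue)}")
    bad_lat = set(df["laterality"].fillna("unknown")) - LATERALITIES
    if bad_lat:
        raise ValidationError(f"unknown laterality values: {sorted(bad_lat)}")
    purity = pd.to_numeric(df["purity"], errors="coerce")
    has_purity = purity.notna()
    if ((purity < 0) | (purity > 1)).any():
        raise ValidationError("purity outside [0, 1]")
    if (has_purity & (df["tissue"] != "tumor")).any():
        offenders = df.loc[has_purity & (df["tissue"] != "tumor"), "sample_id"].tolist()
        raise ValidationError(f"purity set on non-tumor samples: {offenders}")
    blood_counts = df[df["tissue"] == "blood"].groupby("patient_id").size()
    if (blood_counts > 1).any():
        raise ValidationError(
            f"patients with >1 blood sample: {blood_counts[blood_counts > 1].index.tolist()}"
        )
    df["purity"] = purity
    return df


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.replace({"purity": {"": np.nan}})
    return validate_sample_sheet(df)


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    out = df[SAMPLE_SHEET_COLUMNS].copy()
    out["purity"] = out["purity"].map(lambda p: "" if pd.isna(p) else f"{float(p):.6g}")
    out.to_csv(path, sep="\t", index=False)


def validate_cnv_segments(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(CNV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"CNV table missing columns: {sorted(missing)}")
    df = df[CNV_COLUMNS].copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    df["cnloh"] = df["cnloh"].astype(str).str.lower().isin({"1", "true", "t", "yes"})
    if (df["start"] > df["end"]).any():
        raise ValidationError("CNV segment with start > end")
    for (sample, chrom), grp in df.groupby(["sample_id", "chrom"], sort=False):
        g = grp.sort_values("start")
        # 1-based inclusive: adjacent segments may touch only at end+1
        if (g["start"].values[1:] <= g["end"].values[:-1]).any():
            raise ValidationError(f"overlapping CNV segments for {sample} on {chrom}")
    return df


def read_cnv_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    return validate_cnv_segments(df)


def write_cnv_segments(df: pd.DataFrame, path: str | Path) -> None:
    out = df[CNV_COLUMNS].copy()
    out["cnloh"] = out["cnloh"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)


def read_germline_variants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(GERMLINE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"germline variant table missing columns: {sorted(missing)}")
    df = df[GERMLINE_COLUMNS].copy()
    df["gene"] = df["gene"].str.upper()
    for col in ("germline_ref", "germline_alt", "tumor_ref", "tumor_alt"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        if (df[col] < 0).any():
            raise ValidationError(f"negative read count in column {col}")
    for col in ("provean", "polyphen"):
        df[col] = df[col].replace("", "missing")
    return df


def write_germline_variants(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_somatic_coding(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(SOMATIC_CODING_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"coding somatic table missing columns: {sorted(missing)}")
    df = df[SOMATIC_CODING_COLUMNS].copy()
    df["gene"] = df["gene"].str.upper()
    df["protein_change"] = df["protein_change"].replace("", np.nan)
    return df


def read_somatic_noncoding(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str, "ref": str, "alt": str})
    missing = set(SOMATIC_NONCODING_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"noncoding somatic table missing columns: {sorted(missing)}")
    df = df[SOMATIC_NONCODING_COLUMNS].copy()
    df["pos"] = df["pos"].astype(np.int64)
    return df


def write_json_report(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, (set, frozenset, tuple)):
            return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
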