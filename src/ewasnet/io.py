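"""Readers and writers for the pipeline's tabular formats.

Matrices travel as TSV (first column = probe id, remaining columns = sample
ids); tables as CSV; missing values are spelled ``NA``.  Genomic coordinates
are stored 1-based and converted to 0-based half-open only at BED export.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    DIET_ITEMS,
    PHENOTYPE_COLUMNS,
    PhenotypeTable,
    ProbeAnnotation,
    SchemaError,
)

__all__ = [
    "read_phenotype",
    "write_phenotype",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "write_hits_bed",
]

MATRIX_KINDS = ("beta", "intensity_M", "intensity_U", "detection_p", "bead_count")

_INT_COLS = ("case", "married", "diet_score", "bp_med", "dm_treat", *DIET_ITEMS)
_FLOAT_COLS = (
    "age", "fasting_hours", "smoking", "alcohol", "activity",
    "bmi", "sbp", "dbp", "tc", "ldl", "hdl", "tg", "glucose",
)


def read_phenotype(path: str | Path) -> PhenotypeTable:
    """Read a phenotype CSV, validating schema and matching structure.

    Missing numeric fields are kept as NaN (flagged, never imputed here).
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"phenotype file {path} missing columns: {missing}")
    for col in _INT_COLS:
        if df[col].isna().any():
            raise SchemaError(f"column {col} has missing values, expected complete 0/1 or counts")
        df[col] = df[col].astype(int)
    for col in _FLOAT_COLS:
        df[col] = df[col].astype(float)
    df["sample_id"] = df["sample_id"].astype(str)
    df["pair_id"] = df["pair_id"].astype(str)
    return PhenotypeTable(df)


def write_phenotype(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.df[list(PHENOTYPE_COLUMNS)].to_csv(path, index=False, na_rep="NA")


def read_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a probe x sample TSV matrix.

    Ragged rows and duplicate probe ids are errors; for ``kind="beta"``
    values outside [0, 1] are rejected.
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}; expected one of {MATRIX_KINDS}")
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        ncol = len(header)
        rows: list[list[str]] = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != ncol:
                raise SchemaError(
                    f"{path}: line {lineno} has {len(row)} fields, expected {ncol}"
                )
            rows.append(row)
    probe_ids = [r[0] for r in rows]
    if len(set(probe_ids)) != len(probe_ids):
        seen: set[str] = set()
        dups = []
        for p in probe_ids:
            if p in seen:
                dups.append(p)
            seen.add(p)
        raise SchemaError(f"{path}: duplicate probe ids {sorted(set(dups))[:5]}")
    data = np.array(
        [[np.nan if v == "NA" else float(v) for v in r[1:]] for r in rows], dtype=float
    )
    df = pd.DataFrame(data, index=pd.Index(probe_ids, name=header[0] or "probe_id"),
                      columns=header[1:])
    if kind == "beta":
        finite = data[np.isfinite(data)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise SchemaError(f"{path}: beta values outside [0, 1]")
    if kind == "bead_count":
        df = df.round().astype(int)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = out.index.name or "probe_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    if "position" in df.columns:
        df["position"] = df["position"].astype(int)
    return ProbeAnnotation(df)


def write_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, index=False, na_rep="NA")


def write_hits_bed(
    results: pd.DataFrame,
    annotation: ProbeAnnotation,
    path: str | Path,
    p_col: str = "p",
) -> None:
    """Export significant CpGs as BED6.

    ``results`` needs a ``probe`` column plus ``p_col``.  The score is
    -10*log10(p), capped at 1000 (0 for p=1).  Coordinates convert from the
    1-based annotation position to 0-based half-open BED intervals.
    """
    missing = [p for p in results["probe"] if p not in annotation.probes]
    if missing:
        raise KeyError(f"probes absent from annotation: {missing}")
    with open(path, "w") as fh:
        for _, row in results.iterrows():
            ann = annotation.table.loc[row["probe"]]
            p = max(float(row[p_col]), 1e-300)
            score = max(0.0, min(1000.0, -10.0 * np.log10(p)))
            chrom = str(ann["chromosome"])
            if not chrom.startswith("chr"):
                chrom = "chr" + chrom
            fh.write(
                f"{chrom}\t{int(ann['position']) - 1}\t{int(ann['position'])}\t"
                f"{row['probe']}\t{score:g}\t.\n"
            )
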