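"""Typed containers for methylation array data and cohort phenotypes.

All probe x sample matrices are pandas DataFrames with probe IDs as the
index and sample IDs as columns; joins between structures are always done
by label, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntensitySet",
    "MethylationMatrix",
    "DetectionStats",
    "ProbeAnnotation",
    "PhenotypeTable",
    "QcReport",
    "SchemaError",
    "MatchingError",
    "PHENOTYPE_COLUMNS",
    "DIET_ITEMS",
    "RELATION_LEVELS",
]

#: the six qualitative diet items that sum to the 0-6 diet score
DIET_ITEMS = (
    "diet_vegetables",
    "diet_fruit",
    "diet_redmeat",
    "diet_soybean",
    "diet_fish",
    "diet_grains",
)

RELATION_LEVELS = ("TSS200", "TSS1500", "Body", "1stExon", "5'UTR", "3'UTR", "intergenic")

PHENOTYPE_COLUMNS = (
    "sample_id",
    "case",
    "pair_id",
    "age",
    "sex",
    "area",
    "fasting_hours",
    "education",
    "married",
    "smoking",
    "alcohol",
    "activity",
    *DIET_ITEMS,
    "diet_score",
    "bmi",
    "sbp",
    "dbp",
    "tc",
    "ldl",
    "hdl",
    "tg",
    "glucose",
    "bp_med",
    "dm_treat",
    "batch",
)


class SchemaError(ValueError):
    """A table is missing a required column or violates declared typing."""


class MatchingError(ValueError):
    """The case-control matching structure is inconsistent (e.g. two cases in a pair)."""


def _check_matrix(df: pd.DataFrame, name: str) -> None:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate probe ids in {name}: {dups[:5]}")
    if df.columns.has_duplicates:
        raise SchemaError(f"duplicate sample ids in {name}")


@dataclass
class IntensitySet:
    """Raw methylated/unmethylated channel intensities for an EPIC-style array.

    Attributes
    ----------
    M, U
        Probe x sample intensity matrices (non-negative, arbitrary units).
    design_type
        Per-probe Infinium chemistry label, ``"I"`` or ``"II"``, indexed by
        probe id.  Type I and II probes have different marginal intensity
        distributions and are normalized separately.
    """

    M: pd.DataFrame
    U: pd.DataFrame
    design_type: pd.Series

    def __post_init__(self) -> None:
        _check_matrix(self.M, "M")
        _check_matrix(self.U, "U")
        if not self.M.index.equals(self.U.index) or not self.M.columns.equals(self.U.columns):
            raise SchemaError("M and U must share probe and sample labels in the same order")
        if (self.M.to_numpy() < 0).any() or (self.U.to_numpy() < 0).any():
            raise SchemaError("intensities must be non-negative")
        self.design_type = self.design_type.reindex(self.M.index)
        if self.design_type.isna().any():
            missing = self.design_type.index[self.design_type.isna()].tolist()
            raise SchemaError(f"design_type missing for probes: {missing[:5]}")
        bad = ~self.design_type.isin(["I", "II"])
        if bad.any():
            raise SchemaError("design_type must be 'I' or 'II'")

    @property
    def probes(self) -> pd.Index:
        return self.M.index

    @property
    def samples(self) -> pd.Index:
        return self.M.columns


@dataclass
class MethylationMatrix:
    """Normalized beta values (methylation fraction in [0, 1]) per probe and sample."""

    beta: pd.DataFrame
    sd_per_probe: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_matrix(self.beta, "beta")
        vals = self.beta.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise SchemaError("beta values must lie in [0, 1]")
        if self.sd_per_probe is None:
            self.sd_per_probe = self.beta.std(axis=1, ddof=1)

    @property
    def probes(self) -> pd.Index:
        return self.beta.index

    @property
    def samples(self) -> pd.Index:
        return self.beta.columns


@dataclass
class DetectionStats:
    """Per-probe-per-sample detection p-values and bead counts."""

    detection_p: pd.DataFrame
    bead_count: pd.DataFrame

    def __post_init__(self) -> None:
        _check_matrix(self.detection_p, "detection_p")
        if self.detection_p.shape != self.bead_count.shape:
            raise SchemaError("detection_p and bead_count shapes differ")
        p = self.detection_p.to_numpy()
        if (p < 0).any() or (p > 1).any():
            raise SchemaError("detection p-values must lie in [0, 1]")
        if (self.bead_count.to_numpy() < 0).any():
            raise SchemaError("bead counts must be non-negative")


@dataclass
class ProbeAnnotation:
    """Probe-level annotation: genomic position (hg19, 1-based), gene context and QC flags.

    ``table`` columns: probe_id, chromosome, position, gene, relation_to_gene,
    is_snp_probe, snp_overlap, cross_hybridizing.
    """

    table: pd.DataFrame

    REQUIRED = (
        "probe_id",
        "chromosome",
        "position",
        "gene",
        "relation_to_gene",
        "is_snp_probe",
        "snp_overlap",
        "cross_hybridizing",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"annotation missing columns: {missing}")
        if self.table["probe_id"].duplicated().any():
            raise SchemaError("duplicate probe ids in annotation")
        for col in ("is_snp_probe", "snp_overlap", "cross_hybridizing"):
            self.table[col] = self.table[col].astype(bool)
        self.table = self.table.set_index("probe_id", drop=False)

    @property
    def probes(self) -> pd.Index:
        return self.table.index


@dataclass
class PhenotypeTable:
    """Per-sample outcome, matched-pair structure, covariates and traits.

    One row per sample.  Each ``pair_id`` occurs at most twice, with exactly
    one case and one control when complete; ``diet_score`` must equal the sum
    of the six diet items.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"phenotype table missing columns: {missing}")
        if self.df["sample_id"].duplicated().any():
            raise SchemaError("duplicate sample ids in phenotype table")
        if not self.df["case"].isin([0, 1]).all():
            raise SchemaError("case must be 0/1")
        counts = self.df.groupby("pair_id")["case"].agg(["size", "sum"])
        if (counts["size"] > 2).any():
            bad = counts.index[counts["size"] > 2].tolist()
            raise MatchingError(f"pair ids occurring more than twice: {bad[:5]}")
        two = counts[counts["size"] == 2]
        if (two["sum"] != 1).any():
            bad = two.index[two["sum"] != 1].tolist()
            raise MatchingError(f"pairs without exactly one case and one control: {bad[:5]}")
        items = self.df[list(DIET_ITEMS)].astype(int)
        if not (items.sum(axis=1) == self.df["diet_score"].astype(int)).all():
            raise SchemaError("diet_score must equal the sum of the six diet items")
        self.df = self.df.set_index("sample_id", drop=False)

    @property
    def samples(self) -> pd.Index:
        return self.df.index

    @property
    def n_pairs(self) -> int:
        return self.df["pair_id"].nunique()

    def subset(self, sample_ids) -> "PhenotypeTable":
        """Row subset by sample id, preserving order of ``sample_ids``."""
        return PhenotypeTable(self.df.loc[list(sample_ids)].reset_index(drop=True))


@dataclass
class QcReport:
    """Audit trail of probe/sample exclusions, rule by rule, in application order."""

    excluded: dict[str, list[str]] = field(default_factory=dict)
    n_input: int = 0
    n_retained: int = 0

    def add_rule(self, rule: str, ids: list[str]) -> None:
        self.excluded[rule] = list(ids)

    @property
    def counts(self) -> dict[str, int]:
        return {rule: len(ids) for rule, ids in self.excluded.items()}

    def all_excluded(self) -> set[str]:
        out: set[str] = set()
        for ids in self.excluded.values():
            out.update(ids)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": rule, "n_excluded": len(ids), "ids": ";".join(map(str, ids))}
            for rule, ids in self.excluded.items()
        ]
        rows.append(
            {"rule": "retained", "n_excluded": self.n_input - self.n_retained, "ids": ""}
        )
        return pd.DataFrame(rows)
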