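"""Probe and sample quality control for EPIC-style methylation data.

Probe exclusion rules, applied in order: (1) assayed-SNP probes;
(2) bead count < 3 in >= 5% of samples; (3) detection p > 0.05 in > 1% of
samples (strict >); (4) SNP-overlapping or cross-hybridizing probes.

Sample exclusion rules: missing rate > 0.01 across CpGs; predicted sex
disagreeing with reported sex; outliers on the first two coordinates of
classical multidimensional scaling (> 5 MAD from the centroid); samples
flagged as belonging to a distinct batch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .datamodel import DetectionStats, PhenotypeTable, ProbeAnnotation, QcReport

__all__ = [
    "probe_qc",
    "sample_qc",
    "predict_sex",
    "duplicate_concordance",
    "mds_coordinates",
]


def probe_qc(
    det: DetectionStats,
    ann: ProbeAnnotation,
    bead_min: int = 3,
    bead_sample_frac: float = 0.05,
    detection_p_threshold: float = 0.05,
    detection_sample_frac: float = 0.01,
) -> tuple[list[str], QcReport]:
    """Apply the probe exclusion rules in declared order.

    The bead-count rule is inclusive at the boundary (failing in exactly 5%
    of samples excludes); the detection rule is strict (> 1% of samples).
    """
    for name, v in (
        ("bead_sample_frac", bead_sample_frac),
        ("detection_p_threshold", detection_p_threshold),
        ("detection_sample_frac", detection_sample_frac),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    probes = det.detection_p.index
    if not probes.equals(det.bead_count.index):
        raise ValueError("detection_p and bead_count probe ids differ")
    ann_sub = ann.table.reindex(probes)
    if ann_sub["probe_id"].isna().any():
        missing = probes[ann_sub["probe_id"].isna()].tolist()
        raise KeyError(f"probes absent from annotation: {missing[:5]}")

    report = QcReport(n_input=len(probes))
    removed: set[str] = set()

    def _apply(rule: str, mask: pd.Series) -> None:
        ids = [p for p in probes[mask.to_numpy()] if p not in removed]
        report.add_rule(rule, ids)
        removed.update(ids)

    n_samples = det.detection_p.shape[1]
    _apply("snp_assay_probe", ann_sub["is_snp_probe"])
    bead_frac = (det.bead_count < bead_min).sum(axis=1) / n_samples
    _apply("low_bead_count", bead_frac >= bead_sample_frac)
    det_frac = (det.detection_p > detection_p_threshold).sum(axis=1) / n_samples
    _apply("detection_failure", det_frac > detection_sample_frac)
    _apply("snp_overlap_or_cross_hybridizing",
           ann_sub["snp_overlap"] | ann_sub["cross_hybridizing"])

    keep = [p for p in probes if p not in removed]
    report.n_retained = len(keep)
    return keep, report


def mds_coordinates(beta: pd.DataFrame, n_coords: int = 2) -> pd.DataFrame:
    """First coordinates of classical MDS on pairwise Euclidean beta distance.

    For Euclidean distances classical scaling equals PCA of the sample
    profiles, computed here from the centered Gram matrix.
    """
    X = beta.to_numpy(dtype=float).T  # samples x probes
    X = np.where(np.isfinite(X), X, np.nanmean(X, axis=0, keepdims=True))
    Xc = X - X.mean(axis=0, keepdims=True)
    G = Xc @ Xc.T
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1][:n_coords]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return pd.DataFrame(coords, index=beta.columns,
                        columns=[f"MDS{i + 1}" for i in range(n_coords)])


def predict_sex(beta: pd.DataFrame, ann: ProbeAnnotation) -> pd.Series:
    """Predict sample sex from mean chrX methylation via a 2-means split.

    The higher-methylation cluster is labelled female (X inactivation raises
    average chrX methylation in females).  Raises if the annotation carries
    no X-chromosome probes.
    """
    chrx = [p for p in beta.index
            if str(ann.table.loc[p, "chromosome"]).lstrip("chr") == "X"]
    if not chrx:
        raise ValueError("no chrX probes in annotation; supply predicted_sex explicitly")
    mean_x = beta.loc[chrx].mean(axis=0).to_numpy().reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(mean_x)
    female_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    return pd.Series(np.where(km.labels_ == female_cluster, "F", "M"),
                     index=beta.columns, name="predicted_sex")


def sample_qc(
    beta_raw: pd.DataFrame,
    phenotype: PhenotypeTable,
    predicted_sex: pd.Series,
    missing_rate_threshold: float = 0.01,
    mds_mad_cutoff: float = 5.0,
    distinct_batches: tuple[str, ...] = (),
) -> tuple[list[str], QcReport]:
    """Apply the sample exclusion rules in declared order."""
    samples = beta_raw.columns
    report = QcReport(n_input=len(samples))
    removed: set[str] = set()

    def _apply(rule: str, ids: list[str]) -> None:
        ids = [s for s in ids if s not in removed]
        report.add_rule(rule, ids)
        removed.update(ids)

    miss = beta_raw.isna().mean(axis=0)
    _apply("high_missing_rate", list(samples[miss > missing_rate_threshold]))

    reported = phenotype.df.loc[samples, "sex"].astype(str)
    pred = predicted_sex.reindex(samples)
    if pred.isna().any():
        raise ValueError("predicted_sex missing for some samples")
    _apply("sex_mismatch", list(samples[(pred != reported).to_numpy()]))

    coords = mds_coordinates(beta_raw)
    center = coords.median(axis=0)
    dist = np.sqrt(((coords - center) ** 2).sum(axis=1))
    mad = np.median(np.abs(dist - np.median(dist)))
    cutoff = np.median(dist) + mds_mad_cutoff * max(mad, 1e-12)
    _apply("mds_outlier", list(samples[(dist > cutoff).to_numpy()]))

    batches = phenotype.df.loc[samples, "batch"].astype(str)
    _apply("distinct_batch", list(samples[batches.isin(distinct_batches).to_numpy()]))

    keep = [s for s in samples if s not in removed]
    report.n_retained = len(keep)
    return keep, report


def duplicate_concordance(
    beta: pd.DataFrame, replicate_pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson correlation across shared probes for each replicate pair."""
    rows = []
    for s1, s2 in replicate_pairs:
        x = beta[s1].to_numpy(dtype=float)
        y = beta[s2].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 shared probes for pair ({s1}, {s2})")
        r = np.corrcoef(x[ok], y[ok])[0, 1]
        rows.append({"sample_1": s1, "sample_2": s2, "r": r, "n_probes": int(ok.sum())})
    out = pd.DataFrame(rows)
    out.attrs["r_min"] = float(out["r"].min())
    out.attrs["r_max"] = float(out["r"].max())
    return out
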