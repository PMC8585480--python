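"""Synthetic nested case-control methylation study with known ground truth.

Emulates the data structure of an EPIC-array incident-CHD study: a matched
case-control cohort with lifestyle and cardiometabolic covariates, and a
probe x sample methylation matrix with bimodal beta marginals, Type I/II
probe chemistry, latent batch/cell-composition factors, planted correlated
co-methylation modules, case-associated probes, and configurable mediation
pathways (exposure -> CpG -> CHD and CpG -> trait -> CHD).

Effects are planted additively on the logit(beta) scale and squashed back,
except the two designated mediation probes, which are generated directly on
the beta scale so that the analytic mediation truth is exact for the linear
mediator model used downstream.

Case status is assigned within each matched pair from the two members'
log-odds (conditional-logistic assignment), so one case per pair always
holds while configured log-odds remain recoverable.

The phenotype and methylation generators share deterministic substreams
(seeded from the master seed plus fixed tags) for the mediation pathway
values, so the CpG values embedded in the methylation matrix are exactly
those that drove the simulated traits and outcomes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    DIET_ITEMS,
    DetectionStats,
    IntensitySet,
    PhenotypeTable,
    ProbeAnnotation,
    RELATION_LEVELS,
)
from . import io as enio

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_cohort",
    "simulate_methylation",
    "simulate_dataset",
    "simulate_mediation_pathway",
    "SMOKING_MEDIATOR_PROBE",
    "SBP_EXPOSURE_PROBE",
]

# reserved probe ids for the two configurable mediation pathways
SMOKING_MEDIATOR_PROBE = "cg90000001"
SBP_EXPOSURE_PROBE = "cg90000002"

# substream tags (np.random.default_rng accepts [seed, tag] sequences)
_TAG_COHORT = 11
_TAG_METH = 12
_TAG_PATHWAY1 = 13
_TAG_PATHWAY2 = 14


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationConfig:
    """All knobs of the generator; every stochastic draw flows from ``seed``."""

    seed: int
    n_pairs: int = 250
    n_probes: int = 10_000
    frac_type_i: float = 0.16

    # latent structure (batch / cell composition / unmeasured confounding)
    n_latent_factors: int = 3
    latent_loading_sparsity: float = 0.3   # fraction of probes loaded per factor
    latent_loading_sd: float = 0.4         # sd of non-zero loadings (logit scale)
    latent_case_corr: float = 0.0          # corr(factor score, case indicator)

    # planted co-methylation modules
    module_sizes: tuple[int, ...] = ()
    module_within_corr: float = 0.7
    module_case_corr: tuple[float, ...] = ()   # per-module driver-case correlation

    # probes shifted by case status
    n_causal_probes: int = 0
    causal_effect_logit: float = 0.25

    # mediation pathway 1: smoking -> CpG -> CHD
    smoking_cpg_effect: float = 0.0        # beta units per cigarette/day
    cpg_chd_log_or: float = 0.0            # log odds per beta unit
    smoking_chd_direct: float = 0.0        # direct log odds per cigarette/day
    smoking_mediator_base: float = 0.45    # baseline beta of the mediator probe
    smoking_mediator_noise: float = 0.03   # residual sd of the mediator probe (beta)

    # mediation pathway 2: CpG -> SBP -> CHD
    cpg_sbp_effect: float = 0.0            # mmHg per beta unit
    sbp_chd_log_or: float = 0.0            # log odds per mmHg
    cpg_sbp_direct_log_or: float = 0.0     # direct log odds per beta unit
    sbp_exposure_base: float = 0.5
    sbp_exposure_noise: float = 0.04       # sd of the exposure probe (beta)
    sbp_residual_sd: float = 12.0          # mmHg

    chd_intercept: float = 0.0             # baseline log odds (pair-relative)
    probe_noise_sd: float = 0.35           # per-probe-per-sample logit noise
    frac_chrx: float = 0.01

    # assay nuisance
    total_intensity: float = 10_000.0
    detection_fail_rate: float = 1e-4
    n_bad_detection_probes: int = 0
    bad_detection_rate: float = 0.05
    bead_fail_rate: float = 1e-4
    n_bad_bead_probes: int = 0
    bad_bead_rate: float = 0.10
    frac_snp_probe: float = 0.0
    frac_snp_overlap: float = 0.0
    frac_cross_hybridizing: float = 0.0
    batch_size: int = 96

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if sum(self.module_sizes) > self.n_probes:
            raise ValueError("module sizes sum exceeds n_probes")
        for name in (
            "frac_type_i", "latent_loading_sparsity", "module_within_corr",
            "detection_fail_rate", "bad_detection_rate", "bead_fail_rate",
            "bad_bead_rate", "frac_chrx", "frac_snp_probe", "frac_snp_overlap",
            "frac_cross_hybridizing",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.latent_case_corr) > 1:
            raise ValueError("latent_case_corr outside [-1, 1]")
        if self.module_case_corr and len(self.module_case_corr) != len(self.module_sizes):
            raise ValueError("module_case_corr length must match module_sizes")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["module_sizes"] = list(self.module_sizes)
        d["module_case_corr"] = list(self.module_case_corr)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("module_sizes", "module_case_corr"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth of one simulated dataset, for parameter-recovery checks."""

    factors: pd.DataFrame                  # sample x latent factor scores
    module_labels: pd.Series               # probe -> module index (0 = none)
    module_drivers: pd.DataFrame           # sample x module driver scores
    causal_effect: pd.Series               # probe -> planted case effect (logit)
    true_proportion_mediated: dict         # pathway -> analytic PM
    trait_effects: dict                    # e.g. {"cpg_sbp_effect": mmHg/beta}

    def to_json_dict(self) -> dict:
        return {
            "true_proportion_mediated": self.true_proportion_mediated,
            "trait_effects": self.trait_effects,
            "n_module_probes": int((self.module_labels > 0).sum()),
            "n_causal_probes": int((self.causal_effect != 0).sum()),
        }


def analytic_proportion_mediated(
    b1: float, t1: float, t2: float, t3: float = 0.0,
    b0: float = 0.0, sigma2: float = 0.0,
    a: float = 1.0, a_star: float = 0.0, cov_term: float = 0.0,
) -> float:
    """Closed-form proportion mediated under the rare-outcome parametric model.

    Mediator model M = b0 + b1*A + eps(sigma2); logistic outcome with linear
    predictor t0 + t1*A + t2*M + t3*A*M.  Returns log(OR_NIE)/log(OR_TE) for
    the exposure contrast (a, a_star).
    """
    log_nie = (t2 * b1 + t3 * b1 * a) * (a - a_star)
    log_nde = (t1 + t3 * (b0 + b1 * a_star + cov_term + t2 * sigma2)) * (a - a_star) \
        + 0.5 * t3 ** 2 * sigma2 * (a ** 2 - a_star ** 2)
    log_te = log_nie + log_nde
    if abs(log_te) < 1e-12:
        return float("nan")
    return log_nie / log_te


def _case_std(case: np.ndarray) -> np.ndarray:
    # case indicator standardized to mean 0, variance 1 (50% prevalence)
    return (case - 0.5) * 2.0


def _corr_with(target: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    z = rng.normal(size=target.shape[0])
    return rho * target + np.sqrt(max(0.0, 1.0 - rho ** 2)) * z


def _pathway_draws(config: SimulationConfig, n: int):
    """Deterministic mediation-pathway residuals shared by both generators."""
    rng1 = np.random.default_rng([config.seed, _TAG_PATHWAY1])
    rng2 = np.random.default_rng([config.seed, _TAG_PATHWAY2])
    eps1 = rng1.normal(0.0, config.smoking_mediator_noise, size=n)
    eps2 = rng2.normal(0.0, config.sbp_exposure_noise, size=n)
    return eps1, eps2


def simulate_cohort(config: SimulationConfig) -> PhenotypeTable:
    """Generate the matched nested case-control phenotype table.

    Pairs share sex, study area, fasting-time stratum and age stratum
    (ages differ by at most 3 years); lifestyle variables use zero-inflated
    or bounded draws; cardiometabolic traits follow linear models with
    Gaussian noise; case status is assigned within each pair from the
    configured log-odds model.
    """
    rng = np.random.default_rng([config.seed, _TAG_COHORT])
    n_pairs = config.n_pairs
    n = 2 * n_pairs

    # matched (pair-level) factors
    sex = np.repeat(rng.binomial(1, 0.44, size=n_pairs), 2)          # 1 = female
    area = np.repeat(rng.integers(1, 11, size=n_pairs), 2)
    fast_stratum = np.repeat(rng.integers(0, 4, size=n_pairs), 2)
    base_age = np.repeat(rng.uniform(35, 70, size=n_pairs), 2)
    age = np.clip(base_age + rng.uniform(-1.5, 1.5, size=n), 30, 79)
    fasting_hours = np.array([2.0, 7.0, 9.0, 11.0])[fast_stratum] + rng.uniform(-1, 1, size=n)
    fasting_hours = np.clip(fasting_hours, 0, 16)

    # individual covariates
    education = rng.integers(0, 3, size=n)
    married = rng.binomial(1, 0.92, size=n)
    smoker = rng.binomial(1, np.where(sex == 1, 0.03, 0.55))
    smoking = smoker * np.round(rng.gamma(4.0, 4.0, size=n))
    drinker = rng.binomial(1, np.where(sex == 1, 0.02, 0.25))
    alcohol = drinker * np.round(rng.gamma(2.0, 15.0, size=n), 1)
    activity = np.round(rng.gamma(4.0, 5.5, size=n), 1)
    item_probs = (0.92, 0.12, 0.80, 0.08, 0.26, 0.24)
    diet = {k: rng.binomial(1, p, size=n) for k, p in zip(DIET_ITEMS, item_probs)}
    diet_score = np.sum([diet[k] for k in DIET_ITEMS], axis=0)
    bmi = np.clip(rng.normal(23.5, 3.2, size=n), 15, 45)

    # mediation pathway values (shared substreams with simulate_methylation)
    eps1, eps2 = _pathway_draws(config, n)
    med_cpg = np.clip(
        config.smoking_mediator_base + config.smoking_cpg_effect * smoking + eps1, 0.0, 1.0
    )
    exp_cpg = np.clip(config.sbp_exposure_base + eps2, 0.0, 1.0)

    # cardiometabolic traits
    sbp = (
        115.0 + 0.5 * (age - 50) + 1.2 * (bmi - 23.5)
        + config.cpg_sbp_effect * (exp_cpg - config.sbp_exposure_base)
        + rng.normal(0, config.sbp_residual_sd, size=n)
    )
    dbp = 75.0 + 0.3 * (age - 50) + 0.8 * (bmi - 23.5) + 0.45 * (sbp - 115.0) / 2 \
        + rng.normal(0, 7.0, size=n)
    tc = 4.6 + 0.02 * (age - 50) + rng.normal(0, 0.9, size=n)
    ldl = np.clip(0.55 * tc + rng.normal(0, 0.3, size=n), 0.3, None)
    hdl = np.clip(rng.normal(1.2, 0.25, size=n), 0.4, None)
    tg = np.round(np.exp(rng.normal(0.6, 0.5, size=n)), 2)
    dm_treat = rng.binomial(1, 0.05, size=n)
    glucose = 5.8 + 3.0 * dm_treat + rng.normal(0, 1.5, size=n)
    bp_med = rng.binomial(1, _expit(-4.0 + 0.045 * (sbp - 120.0)))

    # outcome model (log odds); case assigned within pair by relative odds
    eta = (
        config.chd_intercept
        + config.smoking_chd_direct * smoking
        + config.cpg_chd_log_or * med_cpg
        + config.cpg_sbp_direct_log_or * exp_cpg
        + config.sbp_chd_log_or * (sbp - 120.0)
    )
    case = np.zeros(n, dtype=int)
    eta_pairs = eta.reshape(n_pairs, 2)
    p_first = 1.0 / (1.0 + np.exp(eta_pairs[:, 1] - eta_pairs[:, 0]))
    first_is_case = rng.uniform(size=n_pairs) < p_first
    case[0::2] = first_is_case.astype(int)
    case[1::2] = 1 - first_is_case.astype(int)

    sample_id = [f"S{i + 1:05d}" for i in range(n)]
    batch = [f"B{i // config.batch_size + 1}" for i in range(n)]
    df = pd.DataFrame(
        {
            "sample_id": sample_id,
            "case": case,
            "pair_id": [f"P{i // 2 + 1:05d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": np.where(sex == 1, "F", "M"),
            "area": area,
            "fasting_hours": np.round(fasting_hours, 1),
            "education": education,
            "married": married,
            "smoking": smoking,
            "alcohol": alcohol,
            "activity": activity,
            **diet,
            "diet_score": diet_score,
            "bmi": np.round(bmi, 1),
            "sbp": np.round(sbp, 1),
            "dbp": np.round(dbp, 1),
            "tc": np.round(tc, 2),
            "ldl": np.round(ldl, 2),
            "hdl": np.round(hdl, 2),
            "tg": tg,
            "glucose": np.round(glucose, 2),
            "bp_med": bp_med,
            "dm_treat": dm_treat,
            "batch": batch,
        }
    )
    return PhenotypeTable(df)


def simulate_methylation(
    phenotype: PhenotypeTable, config: SimulationConfig
) -> tuple[IntensitySet, DetectionStats, ProbeAnnotation, TruthRecord]:
    """Generate intensities, detection stats, annotation and ground truth.

    Probe baselines are drawn from a bimodal logit mixture; latent factors,
    module drivers and case effects add on the logit scale; beta converts to
    intensities as M = beta*T, U = (1-beta)*T with a per-sample, per-design-
    type intensity scale T.
    """
    rng = np.random.default_rng([config.seed, _TAG_METH])
    n_probes, n = config.n_probes, len(phenotype.samples)
    samples = phenotype.samples
    case = phenotype.df["case"].to_numpy(dtype=float)
    female = (phenotype.df["sex"] == "F").to_numpy(dtype=float)
    smoking = phenotype.df["smoking"].to_numpy(dtype=float)

    probes = pd.Index([f"cg{i + 1:08d}" for i in range(n_probes)], name="probe_id")

    # bimodal baseline on the logit scale
    comp = rng.choice(3, size=n_probes, p=[0.45, 0.45, 0.10])
    mu = np.where(
        comp == 0,
        rng.normal(-2.5, 0.6, size=n_probes),
        np.where(comp == 1, rng.normal(2.5, 0.6, size=n_probes), rng.normal(0, 1.0, size=n_probes)),
    )

    logit = np.tile(mu[:, None], (1, n))

    # latent batch / cell-composition factors
    K = config.n_latent_factors
    factors = np.zeros((n, K))
    cs = _case_std(case)
    for k in range(K):
        factors[:, k] = _corr_with(cs, config.latent_case_corr, rng)
    loadings = np.zeros((n_probes, K))
    for k in range(K):
        loaded = rng.uniform(size=n_probes) < config.latent_loading_sparsity
        loadings[loaded, k] = rng.normal(0, config.latent_loading_sd, size=loaded.sum())
    logit += loadings @ factors.T

    # planted co-methylation modules: contiguous probe blocks after the
    # reserved mediation probes; module probes get mid-range baselines so the
    # logistic squash stays near-linear and the planted correlation survives
    module_labels = np.zeros(n_probes, dtype=int)
    drivers = np.zeros((n, len(config.module_sizes)))
    r = config.module_within_corr
    a_load = config.probe_noise_sd * np.sqrt(r / (1.0 - r)) if r < 1 else 10.0
    pos = 2  # probes 0,1 reserved for mediation pathways
    for m, size in enumerate(config.module_sizes):
        rho_m = config.module_case_corr[m] if config.module_case_corr else 0.0
        drivers[:, m] = _corr_with(cs, rho_m, rng)
        idx = np.arange(pos, pos + size)
        module_labels[idx] = m + 1
        mu_mod = rng.normal(0.0, 0.8, size=size)
        logit[idx, :] = mu_mod[:, None] + a_load * drivers[:, m][None, :]
        pos += size

    # case-shifted (causal) probes, placed after the modules
    causal_effect = np.zeros(n_probes)
    if config.n_causal_probes:
        idx = np.arange(pos, pos + config.n_causal_probes)
        causal_effect[idx] = config.causal_effect_logit
        logit[idx, :] += config.causal_effect_logit * case[None, :]
        pos += config.n_causal_probes

    # chrX probes carry a sex signal used by predicted-sex QC
    n_chrx = int(round(config.frac_chrx * n_probes))
    chrx_idx = np.arange(pos, pos + n_chrx)
    logit[chrx_idx, :] += 1.5 * female[None, :]

    # per-cell noise and squash
    logit += rng.normal(0, config.probe_noise_sd, size=(n_probes, n))
    beta = _expit(logit)

    # overwrite the two reserved mediation probes on the beta scale
    eps1, eps2 = _pathway_draws(config, n)
    beta[0, :] = np.clip(
        config.smoking_mediator_base + config.smoking_cpg_effect * smoking + eps1, 0.0, 1.0
    )
    beta[1, :] = np.clip(config.sbp_exposure_base + eps2, 0.0, 1.0)
    probes = probes.copy()
    probe_list = probes.tolist()
    probe_list[0] = SMOKING_MEDIATOR_PROBE
    probe_list[1] = SBP_EXPOSURE_PROBE
    probes = pd.Index(probe_list, name="probe_id")

    # intensities
    design_type = np.where(rng.uniform(size=n_probes) < config.frac_type_i, "I", "II")
    design_type[:2] = "II"
    scale = {
        "I": config.total_intensity * 1.25 * np.exp(rng.normal(0, 0.1, size=n)),
        "II": config.total_intensity * np.exp(rng.normal(0, 0.1, size=n)),
    }
    T = np.where(design_type[:, None] == "I", scale["I"][None, :], scale["II"][None, :])
    M = beta * T
    U = (1.0 - beta) * T

    # detection p-values: near zero except planted failures
    det_rate = np.full(n_probes, config.detection_fail_rate)
    if config.n_bad_detection_probes:
        bad = rng.choice(np.arange(2, n_probes), size=config.n_bad_detection_probes, replace=False)
        det_rate[bad] = config.bad_detection_rate
    fail = rng.uniform(size=(n_probes, n)) < det_rate[:, None]
    detection_p = rng.uniform(0, 1e-6, size=(n_probes, n))
    detection_p[fail] = rng.uniform(0.05, 1.0, size=int(fail.sum()))

    # bead counts: Poisson-like with a floor of 3, planted low-bead failures
    bead = rng.poisson(14.0, size=(n_probes, n)) + 3
    bead_rate = np.full(n_probes, config.bead_fail_rate)
    if config.n_bad_bead_probes:
        badb = rng.choice(np.arange(2, n_probes), size=config.n_bad_bead_probes, replace=False)
        bead_rate[badb] = config.bad_bead_rate
    low = rng.uniform(size=(n_probes, n)) < bead_rate[:, None]
    bead[low] = rng.integers(1, 3, size=int(low.sum()))

    # annotation
    chromosome = rng.choice([str(c) for c in range(1, 23)], size=n_probes)
    chromosome[chrx_idx] = "X"
    chromosome[:2] = ["6", "9"]
    position = rng.integers(1_000_000, 200_000_000, size=n_probes)
    flags = {
        "is_snp_probe": rng.uniform(size=n_probes) < config.frac_snp_probe,
        "snp_overlap": rng.uniform(size=n_probes) < config.frac_snp_overlap,
        "cross_hybridizing": rng.uniform(size=n_probes) < config.frac_cross_hybridizing,
    }
    for v in flags.values():
        v[:2] = False
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": probes,
                "chromosome": chromosome,
                "position": position,
                "gene": [f"GENE{i % 5000 + 1}" for i in range(n_probes)],
                "relation_to_gene": rng.choice(RELATION_LEVELS, size=n_probes),
                **flags,
            }
        )
    )

    intensity = IntensitySet(
        M=pd.DataFrame(M, index=probes, columns=samples),
        U=pd.DataFrame(U, index=probes, columns=samples),
        design_type=pd.Series(design_type, index=probes),
    )
    det = DetectionStats(
        detection_p=pd.DataFrame(detection_p, index=probes, columns=samples),
        bead_count=pd.DataFrame(bead, index=probes, columns=samples),
    )

    sigma1_sq = config.smoking_mediator_noise ** 2
    pm1 = analytic_proportion_mediated(
        b1=config.smoking_cpg_effect, t1=config.smoking_chd_direct,
        t2=config.cpg_chd_log_or, sigma2=sigma1_sq,
    ) if (config.smoking_cpg_effect and config.cpg_chd_log_or) else float("nan")
    pm2 = analytic_proportion_mediated(
        b1=config.cpg_sbp_effect, t1=config.cpg_sbp_direct_log_or,
        t2=config.sbp_chd_log_or, sigma2=config.sbp_residual_sd ** 2,
    ) if (config.cpg_sbp_effect and config.sbp_chd_log_or) else float("nan")

    truth = TruthRecord(
        factors=pd.DataFrame(factors, index=samples,
                             columns=[f"F{k + 1}" for k in range(K)]),
        module_labels=pd.Series(module_labels, index=probes, name="module"),
        module_drivers=pd.DataFrame(
            drivers, index=samples,
            columns=[f"M{m + 1}" for m in range(len(config.module_sizes))],
        ),
        causal_effect=pd.Series(causal_effect, index=probes, name="causal_effect"),
        true_proportion_mediated={"smoking_cpg_chd": pm1, "cpg_sbp_chd": pm2},
        trait_effects={"cpg_sbp_effect": config.cpg_sbp_effect},
    )
    return intensity, det, annotation, truth


def simulate_dataset(config: SimulationConfig, outdir: str | Path, force: bool = False) -> Path:
    """Write a complete simulated bundle (inputs + truth sidecar) to ``outdir``.

    Refuses a non-empty output directory unless ``force``.  Output is
    byte-identical for identical configs.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty; pass force=True to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)

    pheno = simulate_cohort(config)
    intensity, det, annotation, truth = simulate_methylation(pheno, config)

    enio.write_phenotype(pheno, outdir / "phenotype.csv")
    enio.write_matrix(intensity.M, outdir / "intensity_M.tsv")
    enio.write_matrix(intensity.U, outdir / "intensity_U.tsv")
    enio.write_matrix(det.detection_p, outdir / "detection_p.tsv")
    enio.write_matrix(det.bead_count, outdir / "bead_count.tsv")
    enio.write_annotation(annotation, outdir / "annotation.csv")
    intensity.design_type.rename("design_type").to_csv(outdir / "design_type.csv")

    truth.factors.to_csv(outdir / "truth_factors.tsv", sep="\t", float_format="%.10g")
    truth.module_labels.to_csv(outdir / "truth_modules.tsv", sep="\t")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {"config": config.to_dict(), **truth.to_json_dict()},
            fh, indent=2, sort_keys=True,
        )
    return outdir


@dataclass
class PathwayData:
    """One simulated exposure/mediator/outcome pathway draw."""

    exposure: np.ndarray
    mediator: np.ndarray
    outcome: np.ndarray
    true_pm: float


def simulate_mediation_pathway(
    n: int,
    seed: int,
    b0: float = 0.0,
    b1: float = 0.15,
    sigma: float = 1.0,
    t0: float = -3.0,
    t1: float = 0.35,
    t2: float = 1.0,
    t3: float = 0.0,
) -> PathwayData:
    """Prospective single-pathway draw with a rare binary outcome.

    With the defaults, log OR_NIE = t2*b1 = 0.15 and log OR_NDE = t1 = 0.35
    per unit exposure, so the analytic proportion mediated is exactly 0.30.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    m = b0 + b1 * a + rng.normal(0, sigma, size=n)
    eta = t0 + t1 * a + t2 * m + t3 * a * m
    y = (rng.uniform(size=n) < _expit(eta)).astype(int)
    pm = analytic_proportion_mediated(b1=b1, t1=t1, t2=t2, t3=t3, b0=b0,
                                      sigma2=sigma ** 2)
    return PathwayData(exposure=a, mediator=m, outcome=y, true_pm=pm)
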