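"""Pipeline orchestration: simulate -> qc -> normalize -> ewas -> network -> mediate.

Stages run in flowchart order, each writing its outputs plus a manifest
recording content hashes of its inputs; a rerun with unchanged inputs is a
per-stage no-op.  Caching is keyed by content hash, never by timestamps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as enio
from .datamodel import MethylationMatrix, IntensitySet, DetectionStats
from .ewas import (
    build_design,
    estimate_n_sv,
    genomic_lambda,
    qq_points,
    run_ewas,
    smart_sva,
    SurrogateVariableSet,
)
from .network import (
    build_modules,
    choose_soft_power,
    detect_sample_outliers,
    module_specific_fdr,
    module_trait_test,
    permutation_module_test,
    select_top_k,
)
from .mediation import mediate
from .normalize import dasen_normalize
from .qc import predict_sex, probe_qc, sample_qc
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in args[0]."""


_KNOWN_KEYS = {
    "data_dir", "out_dir", "seed", "simulate", "simulation",
    "qc", "network", "ewas", "mediation", "sensitivity_exclude_bp_med",
}
_QC_KEYS = {"bead_sample_frac", "detection_sample_frac", "missing_rate_threshold",
            "mds_mad_cutoff", "distinct_batches"}
_EWAS_KEYS = {"n_sv"}
_NETWORK_KEYS = {"k", "min_module_size", "merge_cut_height", "block_size",
                 "power", "permutations"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    data_dir: str
    out_dir: str
    seed: int
    simulate: bool = False
    simulation: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    ewas: dict = field(default_factory=lambda: {"n_sv": "auto"})
    network: dict = field(default_factory=lambda: {"k": 2000})
    mediation: list = field(default_factory=list)
    sensitivity_exclude_bp_med: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory, never defaulted silently")
        for d, allowed, name in ((self.qc, _QC_KEYS, "qc"),
                                 (self.ewas, _EWAS_KEYS, "ewas"),
                                 (self.network, _NETWORK_KEYS, "network")):
            unknown = set(d) - allowed
            if unknown:
                raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class _Stage:
    """Content-hash cached stage runner."""

    def __init__(self, out_dir: Path, name: str, verbose: bool = False):
        self.name = name
        self.manifest_path = out_dir / f"{name}.manifest.json"
        self.verbose = verbose

    def up_to_date(self, inputs: dict, outputs: list[Path]) -> bool:
        if not self.manifest_path.exists():
            return False
        if not all(p.exists() for p in outputs):
            return False
        try:
            recorded = json.loads(self.manifest_path.read_text())
        except json.JSONDecodeError:
            return False
        return recorded.get("inputs") == inputs and (
            recorded.get("outputs")
            == {str(p): _hash_file(p) for p in outputs}
        )

    def record(self, inputs: dict, outputs: list[Path]) -> None:
        self.manifest_path.write_text(json.dumps(
            {"stage": self.name, "inputs": inputs,
             "outputs": {str(p): _hash_file(p) for p in outputs}},
            indent=2, sort_keys=True,
        ))


def run_pipeline(config: PipelineConfig, verbose: bool = False) -> dict:
    """Execute all configured stages; returns {stage: "ran"|"cached"}.

    Any stage failure raises :class:`StageError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_dir = Path(config.data_dir)
    status: dict[str, str] = {}

    def log(msg: str) -> None:
        if verbose:
            print(f"[ewasnet] {msg}")

    # ---- simulate -------------------------------------------------------
    if config.simulate:
        stage = _Stage(out_dir, "simulate", verbose)
        sim_cfg = SimulationConfig.from_dict({"seed": config.seed, **config.simulation})
        inputs = {"config": _hash_obj(sim_cfg.to_dict())}
        outputs = [data_dir / "phenotype.csv", data_dir / "intensity_M.tsv"]
        if stage.up_to_date(inputs, outputs):
            status["simulate"] = "cached"
        else:
            try:
                simulate_dataset(sim_cfg, data_dir, force=True)
            except Exception as exc:
                raise StageError("simulate", str(exc)) from exc
            stage.record(inputs, outputs)
            status["simulate"] = "ran"
        log(f"simulate: {status['simulate']}")

    input_files = {
        name: data_dir / fname
        for name, fname in [
            ("phenotype", "phenotype.csv"), ("M", "intensity_M.tsv"),
            ("U", "intensity_U.tsv"), ("detection_p", "detection_p.tsv"),
            ("bead_count", "bead_count.tsv"), ("annotation", "annotation.csv"),
            ("design_type", "design_type.csv"),
        ]
    }
    for name, p in input_files.items():
        if not p.exists():
            raise StageError("qc", f"missing input file {p}")
    input_hashes = {k: _hash_file(p) for k, p in input_files.items()}

    # ---- qc + normalize -------------------------------------------------
    beta_path = out_dir / "beta.tsv"
    qc_outputs = [out_dir / "qc_probes.csv", out_dir / "qc_samples.csv", beta_path]
    stage = _Stage(out_dir, "qc_normalize", verbose)
    qc_inputs = {**input_hashes, "qc_config": _hash_obj(config.qc)}
    if stage.up_to_date(qc_inputs, qc_outputs):
        status["qc_normalize"] = "cached"
    else:
        try:
            pheno = enio.read_phenotype(input_files["phenotype"])
            M = enio.read_matrix(input_files["M"], "intensity_M")
            U = enio.read_matrix(input_files["U"], "intensity_U")
            det = DetectionStats(
                detection_p=enio.read_matrix(input_files["detection_p"], "detection_p"),
                bead_count=enio.read_matrix(input_files["bead_count"], "bead_count"),
            )
            ann = enio.read_annotation(input_files["annotation"])
            design_type = pd.read_csv(input_files["design_type"], index_col=0)["design_type"]
            intensity = IntensitySet(M=M, U=U, design_type=design_type)

            qc_opts = dict(config.qc)
            distinct = tuple(qc_opts.pop("distinct_batches", ()))
            probe_opts = {k: qc_opts[k] for k in ("bead_sample_frac", "detection_sample_frac")
                          if k in qc_opts}
            sample_opts = {k: qc_opts[k] for k in ("missing_rate_threshold", "mds_mad_cutoff")
                           if k in qc_opts}
            keep_probes, probe_report = probe_qc(det, ann, **probe_opts)
            raw_beta = M / (M + U + 100.0)
            psex = predict_sex(raw_beta, ann)
            keep_samples, sample_report = sample_qc(
                raw_beta.loc[keep_probes], pheno, psex,
                distinct_batches=distinct, **sample_opts,
            )
            # keep matched pairs intact: drop the partner of excluded samples
            kept = pheno.df.loc[keep_samples]
            full_pairs = kept["pair_id"].value_counts()
            keep_samples = list(kept[kept["pair_id"].isin(
                full_pairs.index[full_pairs == 2])].index)

            probe_report.to_frame().to_csv(out_dir / "qc_probes.csv", index=False)
            sample_report.to_frame().to_csv(out_dir / "qc_samples.csv", index=False)

            filtered = IntensitySet(
                M=M.loc[keep_probes, keep_samples],
                U=U.loc[keep_probes, keep_samples],
                design_type=design_type.loc[keep_probes],
            )
            norm = dasen_normalize(filtered)
            enio.write_matrix(norm.beta, beta_path)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("qc_normalize", str(exc)) from exc
        stage.record(qc_inputs, qc_outputs)
        status["qc_normalize"] = "ran"
    log(f"qc_normalize: {status['qc_normalize']}")

    # ---- ewas -----------------------------------------------------------
    ewas_path = out_dir / "ewas.tsv"
    sv_path = out_dir / "surrogate_variables.tsv"
    infl_path = out_dir / "inflation.json"
    stage = _Stage(out_dir, "ewas", verbose)
    ewas_inputs = {"beta": _hash_file(beta_path),
                   "phenotype": input_hashes["phenotype"],
                   "ewas_config": _hash_obj(config.ewas),
                   "sensitivity": config.sensitivity_exclude_bp_med}
    ewas_outputs = [ewas_path, sv_path, infl_path]
    if stage.up_to_date(ewas_inputs, ewas_outputs):
        status["ewas"] = "cached"
    else:
        try:
            pheno = enio.read_phenotype(input_files["phenotype"])
            beta_df = enio.read_matrix(beta_path, "beta")
            samples = [s for s in beta_df.columns]
            if config.sensitivity_exclude_bp_med:
                keep = pheno.df.loc[samples]
                keep = keep[keep["bp_med"] == 0]
                pairs = keep["pair_id"].value_counts()
                samples = list(keep[keep["pair_id"].isin(pairs.index[pairs == 2])].index)
                beta_df = beta_df[samples]
            sub_pheno = pheno.subset(samples)
            meth = MethylationMatrix(beta=beta_df)
            design = build_design(sub_pheno)
            n_sv_policy = config.ewas.get("n_sv", "auto")
            n_sv = estimate_n_sv(meth, design) if n_sv_policy == "auto" else int(n_sv_policy)
            svs = smart_sva(meth, design, design.without_case(), n_sv) if n_sv else \
                SurrogateVariableSet(sv=pd.DataFrame(index=meth.samples))
            res = run_ewas(meth, design, svs)
            res.to_csv(ewas_path, sep="\t", index=False, float_format="%.10g")
            svs.sv.to_csv(sv_path, sep="\t", float_format="%.10g")
            exp_lp, obs_lp = qq_points(res["p"])
            pd.DataFrame({"expected_neglog10p": exp_lp,
                          "observed_neglog10p": obs_lp}).to_csv(
                out_dir / "qq.tsv", sep="\t", index=False, float_format="%.6g")
            infl_path.write_text(json.dumps({
                "n_sv": int(n_sv),
                "lambda": genomic_lambda(res["p"]),
                "n_probes": int(len(res)),
                "n_samples": int(len(samples)),
            }, indent=2))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("ewas", str(exc)) from exc
        stage.record(ewas_inputs, ewas_outputs)
        status["ewas"] = "ran"
    log(f"ewas: {status['ewas']}")

    # ---- network --------------------------------------------------------
    modules_path = out_dir / "modules.tsv"
    eig_path = out_dir / "eigengenes.tsv"
    modtest_path = out_dir / "module_trait.tsv"
    stage = _Stage(out_dir, "network", verbose)
    net_inputs = {"beta": _hash_file(beta_path), "ewas": _hash_file(ewas_path),
                  "network_config": _hash_obj(config.network), "seed": config.seed}
    net_outputs = [modules_path, eig_path, modtest_path]
    if stage.up_to_date(net_inputs, net_outputs):
        status["network"] = "cached"
    else:
        try:
            pheno = enio.read_phenotype(input_files["phenotype"])
            beta_df = enio.read_matrix(beta_path, "beta")
            res = pd.read_csv(ewas_path, sep="\t")
            svs_df = pd.read_csv(sv_path, sep="\t", index_col=0)
            svs = SurrogateVariableSet(sv=svs_df)
            k = min(int(config.network.get("k", 2000)), len(res))
            top = select_top_k(res, k)
            sub = beta_df.loc[top]
            outliers = detect_sample_outliers(sub)
            samples = [s for s in sub.columns if s not in set(outliers)]
            sub = sub[samples]
            sub_pheno = pheno.subset(samples)
            power = config.network.get("power") or choose_soft_power(sub)
            mods = build_modules(
                sub, power,
                min_module_size=int(config.network.get("min_module_size", 30)),
                merge_cut_height=float(config.network.get("merge_cut_height", 0.25)),
                block_size=int(config.network.get("block_size", 5000)),
                seed=config.seed,
            )
            design = build_design(sub_pheno)
            sv_sub = SurrogateVariableSet(sv=svs.sv.loc[samples]) if svs.n_sv else None
            rows = []
            n_mod = max(len(mods.module_names), 1)
            for m in mods.module_names:
                coefc, p = module_trait_test(mods.eigengenes[m], design, sv_sub)
                rows.append({"module": m, "n_probes": int((mods.labels == m).sum()),
                             "coef": coefc, "p": p,
                             "bonferroni_significant": bool(p < 0.05 / n_mod)})
            trait = pd.DataFrame(rows) if rows else pd.DataFrame(
                columns=["module", "n_probes", "coef", "p", "bonferroni_significant"])
            mods.labels.to_csv(modules_path, sep="\t")
            mods.eigengenes.to_csv(eig_path, sep="\t", float_format="%.10g")
            trait.to_csv(modtest_path, sep="\t", index=False)
            # module-specific FDR for significant modules
            sig = trait[trait["bonferroni_significant"].astype(bool)] if len(trait) \
                else trait
            fdr_frames = []
            for m in sig["module"]:
                mf = module_specific_fdr(res, mods.probes_in(m)).reset_index()
                mf["module"] = m
                fdr_frames.append(mf)
            if fdr_frames:
                pd.concat(fdr_frames).to_csv(out_dir / "module_fdr.tsv",
                                             sep="\t", index=False)
            B = int(config.network.get("permutations", 0))
            if B:
                meth = MethylationMatrix(beta=beta_df[samples])
                perm = permutation_module_test(
                    meth, sub_pheno, sv_sub, k=k, B=B, seed=config.seed, power=power)
                (out_dir / "permutation.json").write_text(json.dumps({
                    "B": B, "observed_min_p": perm.observed_min_p,
                    "empirical_p": perm.empirical_p,
                    "permuted_min_p": perm.permuted_min_p.tolist(),
                }, indent=2))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("network", str(exc)) from exc
        stage.record(net_inputs, net_outputs)
        status["network"] = "ran"
    log(f"network: {status['network']}")

    # ---- mediation ------------------------------------------------------
    if config.mediation:
        med_path = out_dir / "mediation.tsv"
        stage = _Stage(out_dir, "mediate", verbose)
        med_inputs = {"beta": _hash_file(beta_path),
                      "phenotype": input_hashes["phenotype"],
                      "spec": _hash_obj(config.mediation), "seed": config.seed}
        if stage.up_to_date(med_inputs, [med_path]):
            status["mediate"] = "cached"
        else:
            try:
                pheno = enio.read_phenotype(input_files["phenotype"])
                beta_df = enio.read_matrix(beta_path, "beta")
                sub_pheno = pheno.subset(list(beta_df.columns))
                rows = []
                for spec in config.mediation:
                    r = mediate(
                        spec["direction"], spec["exposure"], spec["mediator"],
                        sub_pheno, beta=beta_df,
                        n_boot=int(spec.get("bootstrap", 0)), seed=config.seed,
                    )
                    rows.append({
                        "direction": spec["direction"], "exposure": spec["exposure"],
                        "mediator": spec["mediator"], "or_te": r.or_te,
                        "or_nde": r.or_nde, "or_nie": r.or_nie,
                        "proportion_mediated": r.proportion_mediated,
                        "p_nie": r.p_nie, "p_proportion": r.p_proportion,
                    })
                pd.DataFrame(rows).to_csv(med_path, sep="\t", index=False,
                                          float_format="%.10g")
            except StageError:
                raise
            except Exception as exc:
                raise StageError("mediate", str(exc)) from exc
            stage.record(med_inputs, [med_path])
            status["mediate"] = "ran"
        log(f"mediate: {status['mediate']}")

    return status
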