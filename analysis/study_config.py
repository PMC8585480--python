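"""Shared configuration for the analysis scripts.

One synthetic study emulating the nested case-control design at desk scale:
250 matched pairs, 10,000 probes, three latent batch/cell-composition
factors mildly correlated with case status, five planted co-methylation
modules (the first case-associated), a block of case-shifted probes, and
both mediation pathways (smoking -> CpG -> CHD with analytic proportion
mediated 0.30; CpG -> SBP -> CHD).
"""

from pathlib import Path

from ewasnet.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
BUNDLE_DIR = ROOT / "scratch" / "study_bundle"
WORK_DIR = ROOT / "scratch" / "study_work"
RESULTS_DIR = ROOT / "results"

SEED = 20

# smoking -> CpG -> CHD: PM = (30 * 1.5e-3) / (0.03 + 30 * 1.5e-3) = 0.60
# per cigarette; with no interaction the proportion is contrast-invariant
STUDY = SimulationConfig(
    seed=SEED,
    n_pairs=250,
    n_probes=10_000,
    n_latent_factors=3,
    latent_case_corr=0.15,
    # modules kept to ~1% of the array: between-sample quantile normalization
    # redistributes any shift of a large probe block across all probes, so a
    # module occupying several percent of a small array would leak into the
    # surrogate variables; real arrays have ~100x more probes per module
    module_sizes=(50, 45, 40, 35, 30),
    module_within_corr=0.7,
    module_case_corr=(0.2, 0.0, 0.0, 0.0, 0.0),
    n_causal_probes=20,
    causal_effect_logit=0.3,
    smoking_cpg_effect=1.5e-3,
    cpg_chd_log_or=30.0,
    smoking_chd_direct=0.03,
    cpg_sbp_effect=120.0,
    sbp_chd_log_or=0.02,
    cpg_sbp_direct_log_or=2.0,
    n_bad_detection_probes=60,
    n_bad_bead_probes=60,
    frac_snp_probe=0.002,
    frac_snp_overlap=0.02,
    frac_cross_hybridizing=0.01,
)
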