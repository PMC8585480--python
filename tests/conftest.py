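"""Shared fixtures: small simulated bundles reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from ewasnet.datamodel import MethylationMatrix
from ewasnet.simulate import SimulationConfig, simulate_cohort, simulate_methylation


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=7,
        n_pairs=60,
        n_probes=800,
        n_latent_factors=2,
        module_sizes=(60,),
        n_causal_probes=10,
        n_bad_detection_probes=15,
        n_bad_bead_probes=15,
        frac_snp_probe=0.01,
        frac_snp_overlap=0.02,
        frac_cross_hybridizing=0.01,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    pheno = simulate_cohort(small_config)
    intensity, det, ann, truth = simulate_methylation(pheno, small_config)
    return {
        "config": small_config,
        "pheno": pheno,
        "intensity": intensity,
        "det": det,
        "ann": ann,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_beta(small_bundle) -> MethylationMatrix:
    inten = small_bundle["intensity"]
    return MethylationMatrix(beta=inten.M / (inten.M + inten.U + 100.0))


@pytest.fixture()
def toy_phenotype_df() -> pd.DataFrame:
    """Two complete matched pairs with valid diet scores."""
    rng = np.random.default_rng(0)
    n = 4
    items = {k: [1, 0, 1, 0] for k in (
        "diet_vegetables", "diet_fruit", "diet_redmeat",
        "diet_soybean", "diet_fish", "diet_grains")}
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "case": [1, 0, 0, 1],
        "pair_id": ["P1", "P1", "P2", "P2"],
        "age": [50.0, 51.0, 60.0, 59.0],
        "sex": ["M", "M", "F", "F"],
        "area": [1, 1, 2, 2],
        "fasting_hours": [9.0, 9.5, 3.0, 2.0],
        "education": [0, 1, 2, 1],
        "married": [1, 1, 1, 0],
        "smoking": [10.0, 0.0, 0.0, 0.0],
        "alcohol": [0.0, 20.0, 0.0, 0.0],
        "activity": [20.0, 25.0, 15.0, 18.0],
        **items,
        "diet_score": [6, 0, 6, 0],
        "bmi": [24.0, 23.0, 26.0, 22.0],
        "sbp": [130.0, 120.0, 140.0, 118.0],
        "dbp": [85.0, 75.0, 90.0, 70.0],
        "tc": [4.8, 4.5, 5.0, 4.2],
        "ldl": [2.5, 2.2, 2.8, 2.0],
        "hdl": [1.2, 1.3, 1.1, 1.4],
        "tg": [2.0, 1.8, 2.5, 1.5],
        "glucose": [5.5, 5.8, 6.0, 5.2],
        "bp_med": [0, 0, 1, 0],
        "dm_treat": [0, 0, 0, 0],
        "batch": ["B1", "B1", "B2", "B2"],
    })
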