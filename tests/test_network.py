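"""Co-methylation network: TOM, tree cut, eigengenes, permutation guard."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ewasnet.datamodel import MethylationMatrix
from ewasnet.ewas import bh_adjust, build_design
from ewasnet.network import (
    build_modules,
    choose_soft_power,
    detect_sample_outliers,
    module_eigengene,
    module_specific_fdr,
    module_trait_test,
    permutation_module_test,
    rank_inverse_normal,
    select_top_k,
    tom_similarity,
)
from ewasnet.simulate import SimulationConfig, simulate_cohort, simulate_methylation


@pytest.fixture(scope="module")
def modular_bundle():
    """Three planted modules plus noise probes; first driver case-associated."""
    cfg = SimulationConfig(seed=51, n_pairs=150, n_probes=1200,
                           n_latent_factors=0,
                           module_sizes=(80, 60, 50),
                           module_within_corr=0.7,
                           module_case_corr=(0.35, 0.0, 0.0))
    pheno = simulate_cohort(cfg)
    inten, _, _, truth = simulate_methylation(pheno, cfg)
    beta = inten.M / (inten.M + inten.U + 100.0)
    return {"pheno": pheno, "beta": beta, "truth": truth}


class TestSelectTopK:
    def _records(self, p, probes=None):
        probes = probes or [f"cg{i}" for i in range(len(p))]
        return pd.DataFrame({"probe": probes, "p": p})

    def test_smallest_k_selected(self):
        out = select_top_k(self._records([0.5, 0.01, 0.3, 0.02, 0.9]), 3)
        assert set(out) == {"cg1", "cg3", "cg2"}

    def test_tie_broken_lexicographically(self):
        out = select_top_k(
            self._records([0.5, 0.01, 0.01], probes=["cgB", "cgC", "cgA"]), 1)
        assert out == ["cgA"]

    def test_k_equal_to_all_is_identity(self):
        rec = self._records([0.1, 0.2, 0.3])
        assert set(select_top_k(rec, 3)) == set(rec["probe"])

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            select_top_k(self._records([0.1]), 0)


@pytest.fixture(scope="module")
def homogeneous_beta():
    cfg = SimulationConfig(seed=66, n_pairs=150, n_probes=800,
                           n_latent_factors=0)
    pheno = simulate_cohort(cfg)
    inten, _, _, _ = simulate_methylation(pheno, cfg)
    return inten.M / (inten.M + inten.U + 100.0)


class TestDetectSampleOutliers:
    def test_no_outliers_on_homogeneous_data(self, homogeneous_beta):
        assert detect_sample_outliers(homogeneous_beta) == []

    def test_one_shifted_sample_detected(self, homogeneous_beta):
        beta = homogeneous_beta.copy()
        victim = beta.columns[7]
        beta[victim] = np.clip(beta[victim] + 0.4, 0, 1)
        assert detect_sample_outliers(beta) == [victim]

    def test_two_shifted_samples_detected(self, homogeneous_beta):
        beta = homogeneous_beta.copy()
        victims = [beta.columns[3], beta.columns[11]]
        for v in victims:
            beta[v] = np.clip(beta[v] + 0.4, 0, 1)
        assert set(detect_sample_outliers(beta)) == set(victims)


class TestTom:
    def test_independent_probes_have_near_zero_overlap(self):
        # hand-checkable 3x3: weak adjacencies, no shared neighbours
        a = np.array([
            [1.0, 0.01, 0.02],
            [0.01, 1.0, 0.015],
            [0.02, 0.015, 1.0],
        ])
        t = tom_similarity(a)
        # e.g. t_01 = (a_02*a_21 + a_01) / (min(k0,k1) + 1 - a_01)
        k = a.sum(axis=0) - 1
        expected_01 = (a[0, 2] * a[2, 1] + a[0, 1]) / (min(k[0], k[1]) + 1 - a[0, 1])
        assert t[0, 1] == pytest.approx(expected_01, abs=1e-12)
        assert np.abs(t - np.eye(3)).max() < 0.05

    def test_symmetric_unit_diagonal_bounded(self, modular_bundle):
        sub = modular_bundle["beta"].iloc[:150].to_numpy()
        adj = np.abs(np.corrcoef(sub)) ** 6
        t = tom_similarity(adj)
        assert np.allclose(t, t.T, atol=1e-12)
        assert np.allclose(np.diag(t), 1.0)
        assert t.min() >= 0.0 and t.max() <= 1.0 + 1e-12


class TestChooseSoftPower:
    def test_structured_data_reaches_criterion(self):
        cfg = SimulationConfig(seed=52, n_pairs=250, n_probes=3000,
                               n_latent_factors=5, latent_loading_sparsity=0.4,
                               latent_loading_sd=0.6,
                               module_sizes=(100, 200, 300),
                               module_within_corr=0.7)
        pheno = simulate_cohort(cfg)
        inten, _, _, _ = simulate_methylation(pheno, cfg)
        beta = inten.M / (inten.M + inten.U + 100.0)
        from ewasnet.network import _connectivity_fit

        power = choose_soft_power(beta)
        assert power <= 20
        corr = np.abs(np.corrcoef(beta.to_numpy()))
        assert _connectivity_fit(corr ** power) >= 0.8

    def test_pure_noise_falls_back_with_warning(self):
        rng = np.random.default_rng(53)
        beta = pd.DataFrame(rng.uniform(0.2, 0.8, size=(200, 60)),
                            index=[f"p{i}" for i in range(200)],
                            columns=[f"s{i}" for i in range(60)])
        with pytest.warns(UserWarning, match="falling back"):
            assert choose_soft_power(beta) == 6

    def test_deterministic_for_same_data(self, modular_bundle):
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            p1 = choose_soft_power(modular_bundle["beta"])
            p2 = choose_soft_power(modular_bundle["beta"])
        assert p1 == p2


class TestBuildModules:
    def test_planted_modules_recovered(self, modular_bundle):
        import warnings as w

        beta, truth = modular_bundle["beta"], modular_bundle["truth"]
        with w.catch_warnings():
            w.simplefilter("ignore")
            mods = build_modules(beta, power=6, seed=0)
        planted = truth.module_labels[truth.module_labels > 0]
        ari = adjusted_rand_score(planted.to_numpy(),
                                  mods.labels.loc[planted.index].to_numpy())
        assert ari >= 0.8

    def test_identical_drivers_merge_into_one_module(self):
        rng = np.random.default_rng(54)
        n = 120
        driver = rng.normal(size=n)
        # two probe blocks sharing one driver: eigengene dissimilarity ~ 0
        probes = driver[None, :] * 0.6 + rng.normal(0, 0.25, size=(80, n))
        beta = pd.DataFrame(1 / (1 + np.exp(-probes)),
                            index=[f"p{i}" for i in range(80)],
                            columns=[f"s{i}" for i in range(n)])
        mods = build_modules(beta, power=6, min_module_size=30, block_size=40,
                             seed=0)
        non_grey = [m for m in mods.module_names]
        assert len(non_grey) == 1

    def test_labels_invariant_to_probe_order(self, modular_bundle):
        import warnings as w

        beta = modular_bundle["beta"]
        rng = np.random.default_rng(55)
        shuffled = beta.iloc[rng.permutation(len(beta))]
        with w.catch_warnings():
            w.simplefilter("ignore")
            m1 = build_modules(beta, power=6, seed=0)
            m2 = build_modules(shuffled, power=6, seed=0)
        common = beta.index
        ari = adjusted_rand_score(m1.labels.loc[common].to_numpy(),
                                  m2.labels.loc[common].to_numpy())
        assert ari == pytest.approx(1.0)

    def test_block_size_below_min_module_rejected(self, modular_bundle):
        with pytest.raises(ValueError, match="block_size"):
            build_modules(modular_bundle["beta"], power=6, min_module_size=30,
                          block_size=10)


class TestModuleEigengene:
    def test_identical_probes_give_shared_profile(self):
        rng = np.random.default_rng(56)
        profile = rng.uniform(0.3, 0.7, size=40)
        beta = pd.DataFrame(np.tile(profile, (5, 1)),
                            index=[f"p{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(40)])
        eig, ve = module_eigengene(beta, list(beta.index))
        z = (profile - profile.mean()) / profile.std(ddof=1)
        r = np.corrcoef(eig, z)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)
        assert ve == pytest.approx(1.0)

    def test_matches_direct_svd(self):
        rng = np.random.default_rng(57)
        X = rng.uniform(0.2, 0.8, size=(3, 4))
        beta = pd.DataFrame(X, index=["a", "b", "c"], columns=list("wxyz"))
        eig, ve = module_eigengene(beta, ["a", "b", "c"])
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1)[:, None]
        _, s, vt = np.linalg.svd(Z, full_matrices=False)
        ref = vt[0] if np.dot(vt[0], Z.mean(axis=0)) >= 0 else -vt[0]
        assert np.allclose(eig.to_numpy(), ref, atol=1e-10)
        assert ve == pytest.approx(s[0] ** 2 / (s ** 2).sum(), abs=1e-12)

    def test_sign_orientation_flips_with_data(self):
        rng = np.random.default_rng(58)
        X = rng.uniform(0.1, 0.9, size=(4, 30))
        beta = pd.DataFrame(X, index=list("abcd"),
                            columns=[f"s{i}" for i in range(30)])
        eig1, _ = module_eigengene(beta, list("abcd"))
        eig2, _ = module_eigengene(1.0 - beta, list("abcd"))
        assert np.allclose(eig1.to_numpy(), -eig2.to_numpy(), atol=1e-10)

    def test_eigengene_maximizes_variance_explained(self):
        rng = np.random.default_rng(59)
        X = rng.uniform(0.2, 0.8, size=(20, 50))
        beta = pd.DataFrame(X, index=[f"p{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(50)])
        eig, ve = module_eigengene(beta, list(beta.index))
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1)[:, None]
        total = (Z ** 2).sum()
        for _ in range(50):
            v = rng.normal(size=50)
            v /= np.linalg.norm(v)
            competitor = ((Z @ v) ** 2).sum() / total
            assert competitor <= ve + 1e-12


class TestModuleTraitTest:
    def test_rank_int_has_standard_moments(self):
        rng = np.random.default_rng(60)
        x = rng.exponential(size=501)
        z = rank_inverse_normal(x)
        assert abs(z.mean()) < 1e-10
        assert z.std(ddof=1) == pytest.approx(1.0, abs=0.01)

    def test_case_linked_eigengene_is_significant(self, modular_bundle):
        pheno = modular_bundle["pheno"]
        rng = np.random.default_rng(61)
        eig = pd.Series(pheno.df["case"].to_numpy(dtype=float)
                        + rng.normal(0, 0.05, len(pheno.samples)),
                        index=pheno.samples)
        design = build_design(pheno)
        _, p = module_trait_test(eig, design, None)
        assert p < 1e-10

    def test_null_eigengene_p_uniform(self, modular_bundle):
        from scipy import stats as sps

        pheno = modular_bundle["pheno"]
        design = build_design(pheno)
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(62_000 + rep)
            eig = pd.Series(rng.normal(size=len(pheno.samples)),
                            index=pheno.samples)
            ps.append(module_trait_test(eig, design, None)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestModuleSpecificFdr:
    def test_brown_module_top_cpg_worked_example(self):
        # 2,106-probe module whose smallest association p is 9.61e-8
        rng = np.random.default_rng(63)
        p = np.concatenate([[9.61e-8], rng.uniform(0.001, 1.0, 2105)])
        probes = [f"cg{i:07d}" for i in range(2106)]
        ewas = pd.DataFrame({"probe": probes, "p": p})
        fdr = module_specific_fdr(ewas, probes)
        assert f"{fdr.iloc[0]:.2E}" == "2.02E-04"

    def test_uniform_module_ps_unchanged(self):
        ewas = pd.DataFrame({"probe": [f"cg{i}" for i in range(24)],
                             "p": [0.001] * 24})
        fdr = module_specific_fdr(ewas, list(ewas["probe"]))
        assert np.allclose(fdr, 0.001)

    def test_equals_bh_with_module_family(self):
        rng = np.random.default_rng(64)
        p = rng.uniform(size=50)
        ewas = pd.DataFrame({"probe": [f"cg{i}" for i in range(50)], "p": p})
        fdr = module_specific_fdr(ewas, list(ewas["probe"]))
        assert np.allclose(fdr.to_numpy(), bh_adjust(p))


class TestPermutationTest:
    def test_empirical_p_formula_and_determinism(self):
        cfg = SimulationConfig(seed=65, n_pairs=60, n_probes=400,
                               n_latent_factors=0, module_sizes=(60,),
                               module_case_corr=(0.6,), module_within_corr=0.7)
        pheno = simulate_cohort(cfg)
        inten, _, _, _ = simulate_methylation(pheno, cfg)
        beta = MethylationMatrix(beta=inten.M / (inten.M + inten.U + 100.0))
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            r1 = permutation_module_test(beta, pheno, None, k=150, B=5, seed=9,
                                         power=6)
            r2 = permutation_module_test(beta, pheno, None, k=150, B=5, seed=9,
                                         power=6)
        assert 1 / 6 <= r1.empirical_p <= 1.0
        assert r1.empirical_p == r2.empirical_p
        assert np.array_equal(r1.permuted_min_p, r2.permuted_min_p)
        # a strongly case-linked planted module should beat every permutation
        assert r1.empirical_p == pytest.approx(1 / 6)

    def test_zero_permutations_rejected(self, modular_bundle):
        beta = MethylationMatrix(beta=modular_bundle["beta"])
        with pytest.raises(ValueError):
            permutation_module_test(beta, modular_bundle["pheno"], None,
                                    k=100, B=0, seed=1)
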