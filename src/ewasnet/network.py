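"""Weighted co-methylation network modules and their association with CHD.

Builds an unsigned weighted network over the top-K association CpGs:
soft-thresholded Pearson adjacency, topological overlap similarity,
average-linkage clustering with a fixed-height tree cut, eigengene-based
module merging, and inverse-normal-transformed eigengene regression on case
status.  A permutation test (shuffling case labels within matching strata
and re-running selection + module construction) guards against selection
bias from choosing the top-K probes on the observed outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .datamodel import MethylationMatrix, PhenotypeTable
from .ewas import DesignMatrix, SurrogateVariableSet, bh_adjust, run_ewas

__all__ = [
    "ModuleSet",
    "PermutationResult",
    "select_top_k",
    "detect_sample_outliers",
    "choose_soft_power",
    "tom_similarity",
    "build_modules",
    "module_eigengene",
    "rank_inverse_normal",
    "module_trait_test",
    "module_specific_fdr",
    "permutation_module_test",
]

GREY = "grey"

#: module label palette, assigned to modules in decreasing size order
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)


@dataclass
class ModuleSet:
    """Probe -> module assignment with eigengenes and association statistics."""

    labels: pd.Series                      # probe -> color label ("grey" = unassigned)
    eigengenes: pd.DataFrame               # sample x module
    variance_explained: dict[str, float]
    power: int
    merge_heights: np.ndarray = field(default_factory=lambda: np.array([]))
    trait_stats: pd.DataFrame | None = None

    @property
    def module_names(self) -> list[str]:
        return [c for c in self.eigengenes.columns]

    def probes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


@dataclass
class PermutationResult:
    """Null distribution of the minimum module-association p-value."""

    B: int
    observed_min_p: float
    permuted_min_p: np.ndarray
    empirical_p: float


def select_top_k(ewas: pd.DataFrame, k: int) -> list[str]:
    """The k probes with smallest association p; ties broken by probe id."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ewas):
        raise ValueError(f"k={k} exceeds number of records {len(ewas)}")
    ranked = ewas.sort_values(["p", "probe"], kind="mergesort")
    return ranked["probe"].head(k).tolist()


def detect_sample_outliers(beta_subset: pd.DataFrame) -> list[str]:
    """Samples separated from the main cluster in average-linkage clustering.

    The dendrogram is cut at mean + 3 sd of the merge heights; clusters of
    size < 3 are flagged as outliers.
    """
    n = beta_subset.shape[1]
    if n < 10:
        raise ValueError("need at least 10 samples")
    X = beta_subset.to_numpy(dtype=float).T
    Z = average(pdist(X, metric="euclidean"))
    heights = Z[:, 2]
    cut = heights.mean() + 3.0 * heights.std(ddof=1)
    labels = fcluster(Z, t=cut, criterion="distance")
    counts = pd.Series(labels).value_counts()
    small = counts.index[counts < 3]
    return [beta_subset.columns[i] for i in range(n) if labels[i] in set(small)]


def _connectivity_fit(adj: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit R^2 of the connectivity distribution."""
    k = adj.sum(axis=0) - 1.0  # exclude self-adjacency
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    centers, freqs = [], []
    for i in range(n_bins):
        mask = (k >= edges[i]) & (k < edges[i + 1])
        if mask.sum() > 0:
            centers.append(k[mask].mean())
            freqs.append(mask.mean())
    if len(centers) < 3:
        return 0.0
    x = np.log10(np.asarray(centers))
    y = np.log10(np.maximum(np.asarray(freqs), 1e-12))
    slope, _, r, _, _ = stats.linregress(x, y)
    r2 = r ** 2
    return float(-r2 if slope > 0 else r2)


def choose_soft_power(
    beta_subset: pd.DataFrame,
    candidate_powers: range = range(1, 21),
    r2_threshold: float = 0.8,
    min_mean_connectivity: float = 1.0,
    fallback: int = 6,
) -> int:
    """Smallest soft-threshold power reaching the scale-free fit criterion.

    A qualifying power must also keep the mean connectivity above
    ``min_mean_connectivity``: degenerate near-empty networks can look
    scale-free while carrying no usable structure.
    """
    if beta_subset.shape[0] < 50:
        raise ValueError("need at least 50 probes to assess scale-free fit")
    corr = np.corrcoef(beta_subset.to_numpy(dtype=float))
    corr = np.abs(np.nan_to_num(corr))
    for power in candidate_powers:
        adj = corr ** power
        mean_k = float((adj.sum(axis=0) - 1.0).mean())
        if mean_k >= min_mean_connectivity and _connectivity_fit(adj) >= r2_threshold:
            return int(power)
    warnings.warn(
        f"no candidate power reached scale-free fit R^2 >= {r2_threshold}; "
        f"falling back to {fallback}", stacklevel=2,
    )
    return fallback


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of an adjacency matrix.

    t_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    connectivity k_i excluding the self term; t_ii = 1.
    """
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(t, 1.0)
    return t


def module_eigengene(beta_subset: pd.DataFrame, probes: list[str]) -> tuple[pd.Series, float]:
    """First principal component of the probe-standardized module matrix.

    The sign is oriented to correlate positively with the module's mean
    standardized profile.  Returns (eigengene, variance explained).
    """
    if len(probes) < 2:
        raise ValueError("module must contain at least 2 probes")
    X = beta_subset.loc[probes].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance probes from eigengene",
                      stacklevel=2)
        X, sd = X[keep], sd[keep]
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    mean_profile = Z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=beta_subset.columns), var_explained


def _cut_tree_modules(
    dist: np.ndarray, probe_ids: list[str], min_module_size: int, cut_frac: float = 0.99
) -> list[list[str]]:
    """Fixed-height tree cut: components at cut_frac * max height, >= min size."""
    Z = average(squareform(dist, checks=False))
    max_h = Z[:, 2].max() if len(Z) else 0.0
    labels = fcluster(Z, t=cut_frac * max_h, criterion="distance")
    out = []
    for lab in np.unique(labels):
        members = [probe_ids[i] for i in np.where(labels == lab)[0]]
        if len(members) >= min_module_size:
            out.append(members)
    return out


def build_modules(
    beta_subset: pd.DataFrame,
    power: int,
    min_module_size: int = 30,
    merge_cut_height: float = 0.25,
    block_size: int = 5000,
    seed: int = 0,
) -> ModuleSet:
    """Blockwise unsigned TOM module detection with eigengene merging.

    Probes are pre-partitioned into blocks of at most ``block_size`` by
    k-means on probe profiles (a memory bound, mirroring blockwise network
    construction); modules found within blocks are merged across blocks
    whenever their eigengene correlation dissimilarity (1 - cor) falls below
    ``merge_cut_height``.  Modules are labelled with the conventional color
    palette in decreasing size order; unassigned probes are "grey".
    """
    if block_size < min_module_size:
        raise ValueError("block_size must be >= min_module_size")
    probes = list(beta_subset.index)
    n_probes = len(probes)
    if n_probes < min_module_size:
        raise ValueError("fewer probes than min_module_size")

    X = beta_subset.to_numpy(dtype=float)
    # block pre-clustering
    if n_probes > block_size:
        n_blocks = int(np.ceil(n_probes / block_size))
        km = KMeans(n_clusters=n_blocks, n_init=3, random_state=seed).fit(X)
        blocks: list[list[int]] = []
        for b in range(n_blocks):
            idx = list(np.where(km.labels_ == b)[0])
            while len(idx) > block_size:
                blocks.append(idx[:block_size])
                idx = idx[block_size:]
            if idx:
                blocks.append(idx)
    else:
        blocks = [list(range(n_probes))]

    raw_modules: list[list[str]] = []
    merge_heights: list[float] = []
    for idx in blocks:
        if len(idx) < min_module_size:
            continue
        sub = X[idx]
        corr = np.corrcoef(sub)
        corr = np.abs(np.nan_to_num(corr))
        adj = corr ** power
        tom = tom_similarity(adj)
        dist = 1.0 - tom
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2  # guard asymmetric rounding
        Z = average(squareform(dist, checks=False))
        merge_heights.extend(Z[:, 2].tolist())
        raw_modules.extend(
            _cut_tree_modules(dist, [probes[i] for i in idx], min_module_size)
        )

    # iterative eigengene merging across blocks
    modules = [list(m) for m in raw_modules]
    while len(modules) > 1:
        eigs = np.array([module_eigengene(beta_subset, m)[0].to_numpy() for m in modules])
        cor = np.corrcoef(eigs)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] < merge_cut_height:
            modules[i] = modules[i] + modules[j]
            del modules[j]
        else:
            break

    modules.sort(key=len, reverse=True)
    labels = pd.Series(GREY, index=pd.Index(probes, name="probe_id"), name="module")
    eigengenes = {}
    var_explained = {}
    for rank, members in enumerate(modules):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels.loc[members] = color
        eig, ve = module_eigengene(beta_subset, members)
        eigengenes[color] = eig
        var_explained[color] = ve
    return ModuleSet(
        labels=labels,
        eigengenes=pd.DataFrame(eigengenes, index=beta_subset.columns),
        variance_explained=var_explained,
        power=power,
        merge_heights=np.asarray(merge_heights),
    )


def rank_inverse_normal(x: pd.Series | np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Blom-offset rank-based inverse normal transform, ties by average rank."""
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - c) / (len(x) + 1.0 - 2.0 * c))


def module_trait_test(
    eigengene: pd.Series,
    design: DesignMatrix,
    svs: SurrogateVariableSet | None = None,
) -> tuple[float, float]:
    """Linear regression of the inverse-normal-transformed eigengene on case status.

    Returns (case coefficient, two-sided p).  The Bonferroni selection
    threshold 0.05 / n_modules is applied by the caller across modules.
    """
    y = pd.Series(rank_inverse_normal(eigengene), index=eigengene.index)
    X = design.frame.loc[y.index]
    if svs is not None and svs.n_sv > 0:
        X = pd.concat([X, svs.sv.loc[y.index]], axis=1)
    fit = sm.OLS(y, X).fit()
    return float(fit.params[design.case_col]), float(fit.pvalues[design.case_col])


def module_specific_fdr(ewas: pd.DataFrame, module_probes: list[str]) -> pd.Series:
    """BH adjustment restricted to one module's probes (family = module size)."""
    sub = ewas.set_index("probe").loc[module_probes]
    return pd.Series(bh_adjust(sub["p"].to_numpy()), index=sub.index, name="module_fdr")


def _shuffle_within_strata(
    case: np.ndarray, strata: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = case.copy()
    for s in np.unique(strata):
        idx = np.where(strata == s)[0]
        out[idx] = case[idx][rng.permutation(len(idx))]
    return out


def permutation_module_test(
    beta: MethylationMatrix,
    phenotype: PhenotypeTable,
    svs: SurrogateVariableSet | None,
    k: int,
    B: int,
    seed: int,
    power: int | None = None,
    min_module_size: int = 30,
    merge_cut_height: float = 0.25,
) -> PermutationResult:
    """Selection-bias guard: does top-K selection alone manufacture modules?

    For each of B permutations the case labels are shuffled within area x sex
    strata (respecting the matched design's exchangeability), the EWAS is
    re-run, the top k probes re-selected, modules rebuilt, and the minimum
    module-association p recorded.  The empirical p compares the observed
    minimum against this null.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    from .ewas import build_design  # local import to avoid cycle at module load

    rng = np.random.default_rng(seed)
    strata = (
        phenotype.df["area"].astype(str) + ":" + phenotype.df["sex"].astype(str)
    ).to_numpy()

    def _min_module_p(pheno: PhenotypeTable) -> float:
        design = build_design(pheno)
        res = run_ewas(beta, design, svs)
        top = select_top_k(res, k)
        sub = beta.beta.loc[top]
        pw = power if power is not None else choose_soft_power(sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mods = build_modules(sub, pw, min_module_size=min_module_size,
                                 merge_cut_height=merge_cut_height)
        if not mods.module_names:
            return 1.0
        ps = [module_trait_test(mods.eigengenes[m], design, svs)[1]
              for m in mods.module_names]
        return float(min(ps))

    observed = _min_module_p(phenotype)
    permuted = np.empty(B)
    for b in range(B):
        df = phenotype.df.copy()
        df["case"] = _shuffle_within_strata(df["case"].to_numpy(), strata, rng)
        df = df.drop(columns=["pair_id"]).assign(pair_id=[f"X{i}" for i in range(len(df))])
        perm_pheno = PhenotypeTable(df.reset_index(drop=True))
        permuted[b] = _min_module_p(perm_pheno)

    emp = (1.0 + float((permuted <= observed).sum())) / (B + 1.0)
    return PermutationResult(B=B, observed_min_p=observed,
                             permuted_min_p=permuted, empirical_p=emp)
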