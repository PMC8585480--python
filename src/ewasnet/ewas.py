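"""Surrogate-variable-adjusted epigenome-wide association analysis.

Per-CpG ordinary least squares of normalized beta on case status plus the
cohort covariates and data-derived surrogate variables (SVs), with
Benjamini-Hochberg FDR, genomic-inflation diagnostics, and per-SD logistic
odds ratios for follow-up interpretation.

The SV machinery follows the iteratively reweighted SVD family of
surrogate variable analysis: the number of SVs comes from a random-matrix
(Marchenko-Pastur) criterion on the design-residualized data, and the SVs
themselves from an SVD of the residual matrix with per-probe empirical-Bayes
weights that up-weight probes showing latent structure and down-weight
probes associated with case status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .datamodel import MethylationMatrix, PhenotypeTable

__all__ = [
    "DesignMatrix",
    "SurrogateVariableSet",
    "build_design",
    "estimate_n_sv",
    "smart_sva",
    "run_ewas",
    "bh_adjust",
    "genomic_lambda",
    "qq_points",
    "or_per_sd",
]

P_FLOOR = 1e-300
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549364...


@dataclass
class DesignMatrix:
    """Numeric sample x covariate matrix with an intercept and a case column."""

    frame: pd.DataFrame
    case_col: str = "case"

    @property
    def samples(self) -> pd.Index:
        return self.frame.index

    def without_case(self) -> "DesignMatrix":
        return DesignMatrix(self.frame.drop(columns=[self.case_col]), case_col="")


@dataclass
class SurrogateVariableSet:
    """Unit-variance surrogate variables plus convergence metadata."""

    sv: pd.DataFrame
    n_iter: int = 0
    converged: bool = True
    max_weight_change: float = 0.0

    @property
    def n_sv(self) -> int:
        return self.sv.shape[1]


def build_design(phenotype: PhenotypeTable, include_case: bool = True) -> DesignMatrix:
    """Dummy-code the cohort covariates into a full-rank design matrix.

    Coding: intercept; case (0/1); age continuous; sex (female=1); study
    area as dummies against the first level; fasting >= 8 h dummy; education
    dummies against the lowest level; married dummy; smoking, alcohol,
    activity, diet score and BMI continuous.  Zero-variance dummies are
    dropped with a warning; genuine collinearity raises.
    """
    df = phenotype.df
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    if include_case:
        cols["case"] = df["case"].to_numpy(dtype=float)
    cols["age"] = df["age"].to_numpy(dtype=float)
    cols["sex_F"] = (df["sex"].astype(str) == "F").to_numpy(dtype=float)
    for cat in ("area", "education"):
        if df[cat].nunique() == 1:
            warnings.warn(f"single-level categorical '{cat}': no dummies coded "
                          "(zero-variance)", stacklevel=2)
    areas = sorted(df["area"].astype(str).unique())
    for a in areas[1:]:
        cols[f"area_{a}"] = (df["area"].astype(str) == a).to_numpy(dtype=float)
    cols["fasting_ge8h"] = (df["fasting_hours"] >= 8).to_numpy(dtype=float)
    edus = sorted(df["education"].astype(str).unique())
    for e in edus[1:]:
        cols[f"education_{e}"] = (df["education"].astype(str) == e).to_numpy(dtype=float)
    cols["married"] = df["married"].to_numpy(dtype=float)
    for c in ("smoking", "alcohol", "activity", "diet_score", "bmi"):
        cols[c] = df[c].to_numpy(dtype=float)

    X = pd.DataFrame(cols, index=df.index)
    zero_var = [c for c in X.columns if c != "intercept" and X[c].nunique() <= 1]
    if zero_var:
        warnings.warn(f"dropping zero-variance design columns: {zero_var}", stacklevel=2)
        X = X.drop(columns=zero_var)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name a minimal set of offending columns by greedy QR-style scan
        bad = []
        kept: list[str] = []
        for c in X.columns:
            trial = X[kept + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(c)
            else:
                bad.append(c)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(X, case_col="case" if include_case else "")


def _projector(X: np.ndarray) -> np.ndarray:
    """Hat matrix X (X'X)^-1 X' via pseudo-inverse."""
    return X @ np.linalg.pinv(X)


def _residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Row-wise residuals of Y (features x samples) on design X (samples x p)."""
    return Y - Y @ _projector(X).T


def estimate_n_sv(beta: MethylationMatrix, design: DesignMatrix) -> int:
    """Estimate the number of surrogate variables by a random-matrix criterion.

    Residualizes every probe on the design, standardizes residual rows, and
    counts eigenvalues of the sample-space correlation structure exceeding
    the Marchenko-Pastur upper edge (1 + sqrt(gamma))^2 with gamma =
    n_samples / n_probes.
    """
    Y = beta.beta.to_numpy(dtype=float)
    X = design.frame.loc[beta.samples].to_numpy(dtype=float)
    m, n = Y.shape
    if m < n:
        raise ValueError(f"need more probes ({m}) than samples ({n})")
    if n <= X.shape[1] + 2:
        raise ValueError("too few samples for the design")
    R = _residualize(Y, X)
    sd = R.std(axis=1, ddof=1)
    keep = sd > 0
    R = (R[keep] - R[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    C = (R.T @ R) / R.shape[0]
    evals = np.linalg.eigvalsh(C)
    # residuals live in an (n - p)-dimensional sample subspace: rescale the
    # spectrum so the noise bulk averages one, and use the effective
    # dimension in the aspect ratio
    df = n - np.linalg.matrix_rank(X)
    evals = evals * df / (n - 1)
    gamma = df / R.shape[0]
    edge = (1.0 + np.sqrt(gamma)) ** 2
    return int((evals > edge).sum())


def _local_fdr_posterior(p: np.ndarray) -> np.ndarray:
    """Posterior probability of being non-null, 1 - local FDR.

    Fits a beta-uniform mixture f(p) = pi0 + (1 - pi0) * a * p^(a-1)
    (0 < a < 1) by maximum likelihood; the smooth density keeps the
    iteratively reweighted SVD stable, unlike binned estimates.
    """
    p = np.clip(p, 1e-12, 1.0)
    logp = np.log(p)

    def nll(theta: np.ndarray) -> float:
        pi0, a = theta
        f = pi0 + (1.0 - pi0) * a * np.exp((a - 1.0) * logp)
        return -float(np.sum(np.log(np.maximum(f, 1e-300))))

    best = optimize.minimize(
        nll, x0=np.array([0.8, 0.3]),
        bounds=[(1e-6, 1.0 - 1e-6), (1e-6, 1.0 - 1e-6)],
        method="L-BFGS-B",
    )
    pi0, a = best.x
    f = pi0 + (1.0 - pi0) * a * np.exp((a - 1.0) * logp)
    lfdr = np.clip(pi0 / f, 0.0, 1.0)
    return 1.0 - lfdr


def _f_pvalues(Y: np.ndarray, X0: np.ndarray, X1: np.ndarray) -> np.ndarray:
    """Row-wise nested-model F-test p-values (X0 nested in X1)."""
    n = Y.shape[1]
    rss0 = (_residualize(Y, X0) ** 2).sum(axis=1)
    rss1 = (_residualize(Y, X1) ** 2).sum(axis=1)
    df1 = X1.shape[1] - X0.shape[1]
    df2 = n - X1.shape[1]
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom for F test")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / df1) / np.maximum(rss1 / df2, 1e-300)
    f = np.clip(f, 0.0, None)
    return stats.f.sf(f, df1, df2)


def smart_sva(
    beta: MethylationMatrix,
    design_full: DesignMatrix,
    design_null: DesignMatrix,
    n_sv: int,
    tol: float = 1e-3,
    max_iter: int = 50,
) -> SurrogateVariableSet:
    """Estimate surrogate variables by iteratively reweighted SVD.

    Probe weights are (posterior evidence of latent association) times
    (1 - posterior evidence of case association); each iteration recomputes
    the SVs as the top right singular vectors of the weighted residual
    matrix.  Stops when the largest weight change falls below ``tol`` or
    after ``max_iter`` iterations (flagged, never silent).
    """
    if n_sv == 0:
        return SurrogateVariableSet(
            sv=pd.DataFrame(index=beta.samples), n_iter=0, converged=True
        )
    if n_sv < 0:
        raise ValueError("n_sv must be >= 0")
    Y = beta.beta.to_numpy(dtype=float)
    Xf = design_full.frame.loc[beta.samples].to_numpy(dtype=float)
    X0 = design_null.frame.loc[beta.samples].to_numpy(dtype=float)
    case = design_full.frame.loc[beta.samples, design_full.case_col].to_numpy()[:, None]

    # initialize from the full-model residual (protects the case signal),
    # but iterate the weighted SVD on the null-model residual so that latent
    # structure correlated with case status remains recoverable
    resid_full = _residualize(Y, Xf)
    resid_full -= resid_full.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(resid_full, full_matrices=False)
    sv = vt[:n_sv].T
    resid = _residualize(Y, X0)
    resid -= resid.mean(axis=1, keepdims=True)

    w = np.ones(Y.shape[0])
    converged = False
    it = 0
    delta = np.inf
    for it in range(1, max_iter + 1):
        p_gam = _f_pvalues(Y, X0, np.column_stack([X0, sv]))
        p_b = _f_pvalues(Y, np.column_stack([X0, sv]), np.column_stack([X0, sv, case]))
        w_new = _local_fdr_posterior(p_gam) * (1.0 - _local_fdr_posterior(p_b))
        delta = float(np.max(np.abs(w_new - w)))
        w = w_new
        weighted = resid * w[:, None]
        _, _, vt = np.linalg.svd(weighted, full_matrices=False)
        sv = vt[:n_sv].T
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"smart_sva did not converge in {max_iter} iterations "
            f"(last max weight change {delta:.2e})", stacklevel=2,
        )

    # unit variance, sign fixed by positive correlation with highest-loading probe
    sv = (sv - sv.mean(axis=0)) / sv.std(axis=0, ddof=1)
    loadings = (resid * w[:, None]) @ sv  # probes x n_sv
    for k in range(n_sv):
        top = int(np.argmax(np.abs(loadings[:, k])))
        r = np.corrcoef(sv[:, k], Y[top])[0, 1]
        if r < 0:
            sv[:, k] *= -1.0
    frame = pd.DataFrame(sv, index=beta.samples,
                         columns=[f"SV{k + 1}" for k in range(n_sv)])
    return SurrogateVariableSet(sv=frame, n_iter=it, converged=converged,
                                max_weight_change=delta)


def run_ewas(
    beta: MethylationMatrix,
    design: DesignMatrix,
    svs: SurrogateVariableSet | None = None,
) -> pd.DataFrame:
    """Per-probe OLS of beta on [design | SVs]; two-sided t test on the case term.

    Returns a tidy frame with columns probe, effect, se, p, fdr, sd, sorted
    by the input probe order.  The effect is the case-minus-control
    difference in normalized beta.
    """
    Y = beta.beta.to_numpy(dtype=float)
    X = design.frame.loc[beta.samples]
    if svs is not None and svs.n_sv > 0:
        X = pd.concat([X, svs.sv.loc[beta.samples]], axis=1)
    Xn = X.to_numpy(dtype=float)
    n, p = Xn.shape
    df_resid = n - p
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    case_idx = list(X.columns).index(design.case_col)

    xtx_inv = np.linalg.pinv(Xn.T @ Xn)
    coef = Y @ Xn @ xtx_inv.T          # probes x p
    resid = Y - coef @ Xn.T
    sigma2 = (resid ** 2).sum(axis=1) / df_resid
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[case_idx, case_idx], 0.0))
    effect = coef[:, case_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, np.inf * np.sign(effect))
    pvals = np.maximum(2.0 * stats.t.sf(np.abs(t), df_resid), P_FLOOR)

    out = pd.DataFrame(
        {
            "probe": beta.probes,
            "effect": effect,
            "se": se,
            "p": pvals,
            "fdr": bh_adjust(pvals),
            "sd": beta.beta.std(axis=1, ddof=1).to_numpy(),
        }
    )
    return out


def bh_adjust(p: np.ndarray | pd.Series, m: int | None = None) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values.

    ``m`` defaults to ``len(p)`` but may be larger, reproducing a
    within-subset adjustment against a bigger test family (e.g. a module's
    probes against the genome-wide count).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    k = len(p)
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"family size m={m} smaller than number of p-values {k}")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, k + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(k)
    out[order] = adjusted
    return out


def genomic_lambda(p: np.ndarray | pd.Series) -> float:
    """Genomic inflation factor: median association chi2 over its null median."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def qq_points(p: np.ndarray | pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Expected and observed -log10 p for a Q-Q plot, ascending."""
    p = np.sort(np.asarray(p, dtype=float))
    n = len(p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)[::-1]
    observed = -np.log10(np.maximum(p, P_FLOOR))[::-1]
    return expected[::-1], observed[::-1]


def or_per_sd(
    beta_probe: pd.Series,
    design_null: DesignMatrix,
    svs: SurrogateVariableSet | None,
    case: pd.Series,
) -> dict:
    """Unconditional logistic OR per SD of methylation, with Wald 95% CI.

    Non-convergence or separation yields a flagged record rather than a
    crash.
    """
    sd = beta_probe.std(ddof=1)
    z = (beta_probe - beta_probe.mean()) / sd
    X = design_null.frame.loc[z.index]
    if svs is not None and svs.n_sv > 0:
        X = pd.concat([X, svs.sv.loc[z.index]], axis=1)
    X = pd.concat([z.rename("meth_sd"), X], axis=1)
    y = case.loc[z.index].astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        coef = fit.params["meth_sd"]
        se = fit.bse["meth_sd"]
        flagged = bool(not fit.mle_retvals.get("converged", True) or not np.isfinite(se)
                       or se > 50)
    except Exception:
        return {"or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "flagged": True}
    return {
        "or": float(np.exp(coef)),
        "ci_low": float(np.exp(coef - 1.959963984540054 * se)),
        "ci_high": float(np.exp(coef + 1.959963984540054 * se)),
        "p": float(fit.pvalues["meth_sd"]),
        "flagged": flagged,
    }
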