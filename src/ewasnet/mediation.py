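"""Risk-factor association and parametric causal mediation.

Two directions are supported, mirroring the two halves of the analysis:
lifestyle -> CpG -> CHD (the CpG mediates a lifestyle exposure) and
CpG -> cardiometabolic trait -> CHD (a trait mediates a CpG).  Both use the
standard parametric pair of models — a linear model for the mediator and a
logistic model for the outcome allowing an exposure-mediator interaction —
and the rare-outcome closed forms for the natural direct and indirect
effects on the odds-ratio scale:

    log OR_NIE = (th2*b1 + th3*b1*a) (a - a*)
    log OR_NDE = (th1 + th3*(b0 + b1*a* + b2'c + th2*s2)) (a - a*)
                 + th3^2 * s2 * (a^2 - a*^2) / 2
    OR_TE = OR_NDE * OR_NIE,  proportion mediated = log OR_NIE / log OR_TE

where (b0, b1, b2, s2) are the mediator model parameters, (th1, th2, th3)
the outcome model's exposure, mediator and interaction coefficients, and c
the conditioning covariate values (their sample means by default).  The
proportion mediated may be negative or exceed one and is reported as is.

Risk-factor models adjust for batch identifiers rather than surrogate
variables, the appropriate choice when methylation is the model outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datamodel import PhenotypeTable

__all__ = [
    "MediationModels",
    "MediationResult",
    "LIFESTYLE_FACTORS",
    "CARDIOMETABOLIC_TRAITS",
    "lifestyle_cpg_association",
    "quartile_trait_association",
    "fit_mediation_models",
    "natural_effects",
    "mediate",
    "adjusted_trait",
]

LIFESTYLE_FACTORS = ("smoking", "alcohol", "activity", "diet_score", "bmi")
CARDIOMETABOLIC_TRAITS = ("sbp", "dbp", "tc", "ldl", "hdl", "tg", "glucose")

SBP_MED_OFFSET = 15.0
DBP_MED_OFFSET = 10.0

_Z975 = stats.norm.ppf(0.975)


def _base_covariates(pheno: PhenotypeTable, extra: tuple[str, ...] = ()) -> pd.DataFrame:
    """Demographic + batch covariate block (no intercept column).

    Categorical columns (area, education, batch) are dummy-coded against
    their first level; zero-variance dummies never arise because only
    observed levels generate columns.
    """
    df = pheno.df
    cols: dict[str, np.ndarray] = {
        "age": df["age"].to_numpy(dtype=float),
        "sex_F": (df["sex"].astype(str) == "F").to_numpy(dtype=float),
        "fasting_ge8h": (df["fasting_hours"] >= 8).to_numpy(dtype=float),
        "married": df["married"].to_numpy(dtype=float),
    }
    for col, prefix in (("area", "area"), ("education", "education"), ("batch", "batch")):
        levels = sorted(df[col].astype(str).unique())
        for lev in levels[1:]:
            cols[f"{prefix}_{lev}"] = (df[col].astype(str) == lev).to_numpy(dtype=float)
    for c in extra:
        cols[c] = df[c].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def adjusted_trait(pheno: PhenotypeTable, trait: str) -> pd.Series:
    """Trait values on the analysis scale.

    Adds 15 mmHg (SBP) or 10 mmHg (DBP) for participants on blood-pressure
    medication; other traits pass through unchanged.
    """
    vals = pheno.df[trait].astype(float).copy()
    if trait == "sbp":
        vals = vals + SBP_MED_OFFSET * pheno.df["bp_med"]
    elif trait == "dbp":
        vals = vals + DBP_MED_OFFSET * pheno.df["bp_med"]
    return vals


def lifestyle_cpg_association(
    beta_hits: pd.DataFrame, pheno: PhenotypeTable
) -> pd.DataFrame:
    """Joint lifestyle model per CpG: methylation ~ all five factors + covariates.

    Returns one row per (CpG, factor) with effect, SE and p.  Marginal
    significance (p < 0.05) is the screen feeding the mediation analysis.
    """
    if beta_hits.shape[0] == 0:
        raise ValueError("empty hit list")
    X = sm.add_constant(_base_covariates(pheno, extra=LIFESTYLE_FACTORS))
    rows = []
    for probe in beta_hits.index:
        y = beta_hits.loc[probe, pheno.samples].astype(float)
        fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        names = list(X.columns)
        for factor in LIFESTYLE_FACTORS:
            i = names.index(factor)
            rows.append(
                {
                    "probe": probe,
                    "factor": factor,
                    "effect": fit.params[i],
                    "se": fit.bse[i],
                    "p": fit.pvalues[i],
                }
            )
    return pd.DataFrame(rows)


def quartile_trait_association(
    cpg_beta: pd.Series, trait: str, pheno: PhenotypeTable
) -> dict:
    """Trait difference between top and bottom methylation quartiles.

    Methylation is cut at its sample quartiles (ties to the lower quartile);
    the trait is regressed on quartile indicators plus covariates and batch.
    The trend p comes from the quartile index (1-4) entered continuously.
    Glucose models additionally adjust for diabetes treatment.
    """
    if trait not in CARDIOMETABOLIC_TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    x = cpg_beta.loc[pheno.samples].to_numpy(dtype=float)
    cuts = np.quantile(x, [0.25, 0.5, 0.75])
    if len(np.unique(cuts)) < 3 or (np.mean(x == cuts[0]) >= 0.25):
        raise ValueError("degenerate methylation quartiles (>= 25% ties)")
    q = np.searchsorted(cuts, x, side="left") + 1  # 1..4, ties to lower quartile

    extra = tuple(f for f in LIFESTYLE_FACTORS)
    if trait == "glucose":
        extra = extra + ("dm_treat",)
    C = _base_covariates(pheno, extra=extra)
    y = adjusted_trait(pheno, trait).to_numpy()

    qd = pd.get_dummies(pd.Categorical(q, categories=[1, 2, 3, 4]), prefix="Q",
                        drop_first=True).astype(float)
    qd.index = pheno.samples
    X = sm.add_constant(pd.concat([qd, C], axis=1))
    fit = sm.OLS(y, X.to_numpy()).fit()
    i = list(X.columns).index("Q_4")
    Xt = sm.add_constant(pd.concat([pd.Series(q, index=pheno.samples, name="q_idx"), C],
                                   axis=1))
    fit_t = sm.OLS(y, Xt.to_numpy()).fit()
    it = list(Xt.columns).index("q_idx")
    return {
        "effect": float(fit.params[i]),
        "se": float(fit.bse[i]),
        "p": float(fit.pvalues[i]),
        "p_trend": float(fit_t.pvalues[it]),
    }


@dataclass
class MediationModels:
    """Fitted mediator (linear) and outcome (logistic) models."""

    b0: float
    b1: float
    b2: pd.Series                 # mediator-model covariate coefficients
    sigma2: float
    t0: float
    t1: float                     # exposure
    t2: float                     # mediator
    t3: float                     # exposure x mediator (0 when disabled)
    cov_mediator: pd.DataFrame    # covariance of (const, exposure, covariates)
    cov_outcome: pd.DataFrame
    covariate_means: pd.Series
    interaction: bool
    outcome_converged: bool = True


def fit_mediation_models(
    exposure: pd.Series,
    mediator: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    interaction: bool = True,
) -> MediationModels:
    """Fit the mediator and outcome regressions on aligned samples."""
    idx = exposure.index
    a = exposure.to_numpy(dtype=float)
    m = mediator.loc[idx].to_numpy(dtype=float)
    y = outcome.loc[idx].to_numpy(dtype=float)
    C = covariates.loc[idx]
    if abs(np.corrcoef(a, m)[0, 1]) > 0.999:
        raise ValueError("exposure and mediator are collinear (|r| > 0.999)")

    Xm = sm.add_constant(pd.concat([exposure.rename("exposure"), C], axis=1))
    med_fit = sm.OLS(m, Xm.to_numpy()).fit()
    med_names = list(Xm.columns)
    sigma2 = float(med_fit.mse_resid)

    parts = [exposure.rename("exposure"), mediator.loc[idx].rename("mediator")]
    if interaction:
        parts.append((exposure * mediator.loc[idx]).rename("exposure_x_mediator"))
    Xo = sm.add_constant(pd.concat(parts + [C], axis=1))
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            out_fit = sm.Logit(y, Xo.to_numpy()).fit(disp=0, maxiter=200)
            converged = bool(out_fit.mle_retvals.get("converged", True))
        except Exception as exc:  # separation etc.
            raise ValueError(f"outcome model failed to fit: {exc}") from exc
    out_names = list(Xo.columns)

    def _p(fit, names, key):
        return float(fit.params[names.index(key)])

    return MediationModels(
        b0=_p(med_fit, med_names, "const"),
        b1=_p(med_fit, med_names, "exposure"),
        b2=pd.Series(med_fit.params[2:], index=med_names[2:]),
        sigma2=sigma2,
        t0=_p(out_fit, out_names, "const"),
        t1=_p(out_fit, out_names, "exposure"),
        t2=_p(out_fit, out_names, "mediator"),
        t3=_p(out_fit, out_names, "exposure_x_mediator") if interaction else 0.0,
        cov_mediator=pd.DataFrame(med_fit.cov_params(), index=med_names,
                                  columns=med_names),
        cov_outcome=pd.DataFrame(out_fit.cov_params(), index=out_names,
                                 columns=out_names),
        covariate_means=C.mean(axis=0),
        interaction=interaction,
        outcome_converged=converged,
    )


@dataclass
class MediationResult:
    """Natural-effect decomposition on the odds-ratio scale."""

    or_te: float
    or_nde: float
    or_nie: float
    ci_nde: tuple[float, float]
    ci_nie: tuple[float, float]
    ci_te: tuple[float, float]
    proportion_mediated: float
    se_proportion: float
    p_nie: float
    p_proportion: float
    a: float
    a_star: float

    def __post_init__(self) -> None:
        # estimator identity, by construction
        assert abs(np.log(self.or_te)
                   - np.log(self.or_nde) - np.log(self.or_nie)) < 1e-12


def _log_effects_and_grads(models: MediationModels, a: float, a_star: float):
    """Point estimates and gradients of (log NDE, log NIE).

    Gradients are with respect to the stacked parameter vector
    (b0, b1, b2..., th1, th2, th3); the two fits are treated as independent.
    """
    b0, b1, t1, t2, t3 = models.b0, models.b1, models.t1, models.t2, models.t3
    s2 = models.sigma2
    c = models.covariate_means
    cov_term = float(models.b2 @ c) if len(models.b2) else 0.0
    d = a - a_star

    log_nie = (t2 * b1 + t3 * b1 * a) * d
    log_nde = (t1 + t3 * (b0 + b1 * a_star + cov_term + t2 * s2)) * d \
        + 0.5 * t3 ** 2 * s2 * (a ** 2 - a_star ** 2)

    names_b = ["b0", "b1"] + [f"b2:{k}" for k in models.b2.index]
    names_t = ["t1", "t2", "t3"]
    g_nie = dict.fromkeys(names_b + names_t, 0.0)
    g_nde = dict.fromkeys(names_b + names_t, 0.0)

    g_nie["b1"] = (t2 + t3 * a) * d
    g_nie["t2"] = b1 * d
    g_nie["t3"] = b1 * a * d

    g_nde["t1"] = d
    g_nde["t2"] = t3 * s2 * d
    g_nde["t3"] = (b0 + b1 * a_star + cov_term + t2 * s2) * d \
        + t3 * s2 * (a ** 2 - a_star ** 2)
    g_nde["b0"] = t3 * d
    g_nde["b1"] = t3 * a_star * d
    for k in models.b2.index:
        g_nde[f"b2:{k}"] = t3 * c[k] * d

    # stacked covariance (mediator block, outcome block), independence assumed
    med_idx = ["const", "exposure"] + list(models.b2.index)
    cov_b = models.cov_mediator.loc[med_idx, med_idx].to_numpy()
    out_keys = ["exposure", "mediator"]
    if models.interaction:
        out_keys.append("exposure_x_mediator")
    cov_t_full = models.cov_outcome.loc[out_keys, out_keys].to_numpy()
    cov_t = np.zeros((3, 3))
    cov_t[: len(out_keys), : len(out_keys)] = cov_t_full
    cov = np.block([
        [cov_b, np.zeros((cov_b.shape[0], 3))],
        [np.zeros((3, cov_b.shape[0])), cov_t],
    ])
    order = names_b + names_t

    def grad_vec(g: dict) -> np.ndarray:
        return np.array([g[k] for k in order])

    return log_nde, log_nie, grad_vec(g_nde), grad_vec(g_nie), cov


def natural_effects(
    models: MediationModels, a: float = 1.0, a_star: float = 0.0
) -> MediationResult:
    """Rare-outcome natural direct/indirect effects with delta-method inference.

    If |log OR_TE| < 1e-8 the proportion mediated is reported as NaN
    (undefined) rather than a spurious ratio.
    """
    log_nde, log_nie, g_nde, g_nie, cov = _log_effects_and_grads(models, a, a_star)
    log_te = log_nde + log_nie
    g_te = g_nde + g_nie

    se_nde = float(np.sqrt(g_nde @ cov @ g_nde))
    se_nie = float(np.sqrt(g_nie @ cov @ g_nie))
    se_te = float(np.sqrt(g_te @ cov @ g_te))
    p_nie = float(2 * stats.norm.sf(abs(log_nie) / se_nie)) if se_nie > 0 else np.nan

    if abs(log_te) < 1e-8:
        pm, se_pm, p_pm = np.nan, np.nan, np.nan
    else:
        pm = log_nie / log_te
        g_pm = (log_te * g_nie - log_nie * g_te) / log_te ** 2
        se_pm = float(np.sqrt(g_pm @ cov @ g_pm))
        p_pm = float(2 * stats.norm.sf(abs(pm) / se_pm)) if se_pm > 0 else np.nan

    return MediationResult(
        or_te=float(np.exp(log_te)),
        or_nde=float(np.exp(log_nde)),
        or_nie=float(np.exp(log_nie)),
        ci_nde=(float(np.exp(log_nde - _Z975 * se_nde)),
                float(np.exp(log_nde + _Z975 * se_nde))),
        ci_nie=(float(np.exp(log_nie - _Z975 * se_nie)),
                float(np.exp(log_nie + _Z975 * se_nie))),
        ci_te=(float(np.exp(log_te - _Z975 * se_te)),
               float(np.exp(log_te + _Z975 * se_te))),
        proportion_mediated=float(pm),
        se_proportion=float(se_pm),
        p_nie=p_nie,
        p_proportion=p_pm,
        a=a,
        a_star=a_star,
    )


def mediate(
    direction: str,
    exposure_name: str,
    mediator_name: str,
    pheno: PhenotypeTable,
    beta: pd.DataFrame | None = None,
    interaction: bool = True,
    a: float | None = None,
    a_star: float | None = None,
    n_boot: int = 0,
    seed: int = 0,
    controls_only_mediator: bool = False,
) -> MediationResult:
    """Run one mediation analysis in either direction.

    ``direction="lifestyle"``: exposure is a phenotype column, mediator a
    CpG (row of ``beta``).  ``direction="trait"``: exposure is a CpG,
    mediator a cardiometabolic trait (BP-medication offsets and diabetes-
    treatment adjustment applied).  Covariates follow the risk-factor model:
    demographics, batch, and the lifestyle factors other than an exposure's
    own, excluding the mediator variable itself.  Default contrast: exposure
    mean vs mean + 1 SD.

    ``n_boot > 0`` replaces the delta-method CI for the proportion mediated
    with a matched-pair bootstrap percentile interval (point estimates are
    unchanged).
    """
    if direction not in ("lifestyle", "trait"):
        raise ValueError("direction must be 'lifestyle' or 'trait'")

    def _assemble(ph: PhenotypeTable, bt: pd.DataFrame | None):
        if direction == "lifestyle":
            expo = ph.df[exposure_name].astype(float)
            med = bt.loc[mediator_name, ph.samples].astype(float)
            lifestyle = tuple(f for f in LIFESTYLE_FACTORS if f != exposure_name)
            C = _base_covariates(ph, extra=lifestyle)
        else:
            expo = bt.loc[exposure_name, ph.samples].astype(float)
            med = adjusted_trait(ph, mediator_name)
            extra = LIFESTYLE_FACTORS
            if mediator_name == "glucose":
                extra = extra + ("dm_treat",)
            C = _base_covariates(ph, extra=extra)
        return expo, med, ph.df["case"].astype(float), C

    exposure, mediator, outcome, C = _assemble(pheno, beta)
    if a_star is None:
        a_star = float(exposure.mean())
    if a is None:
        a = a_star + float(exposure.std(ddof=1))

    if controls_only_mediator:
        # fit the mediator model on controls only (rare-outcome correctness),
        # then refit jointly for the outcome model
        ctrl = pheno.df.index[pheno.df["case"] == 0]
        models_ctrl = fit_mediation_models(
            exposure.loc[ctrl], mediator.loc[ctrl], outcome.loc[ctrl].astype(float) * 0,
            C.loc[ctrl], interaction=False,
        )
        models = fit_mediation_models(exposure, mediator, outcome, C,
                                      interaction=interaction)
        models.b0, models.b1 = models_ctrl.b0, models_ctrl.b1
        models.b2, models.sigma2 = models_ctrl.b2, models_ctrl.sigma2
        models.cov_mediator = models_ctrl.cov_mediator
    else:
        models = fit_mediation_models(exposure, mediator, outcome, C,
                                      interaction=interaction)
    result = natural_effects(models, a=a, a_star=a_star)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        pairs = pheno.df["pair_id"].unique()
        pms = []
        for _ in range(n_boot):
            chosen = rng.choice(pairs, size=len(pairs), replace=True)
            sel = []
            for p in chosen:
                sel.extend(pheno.df.index[pheno.df["pair_id"] == p].tolist())
            df_b = pheno.df.loc[sel].copy()
            df_b["sample_id"] = [f"R{i}" for i in range(len(df_b))]
            df_b["pair_id"] = np.repeat(np.arange(len(chosen)).astype(str),
                                        [int((pheno.df["pair_id"] == p).sum())
                                         for p in chosen])
            ph_b = PhenotypeTable(df_b.reset_index(drop=True))
            bt_b = None
            if beta is not None:
                bt_b = beta.loc[:, sel].copy()
                bt_b.columns = ph_b.samples
            try:
                e_b, m_b, y_b, C_b = _assemble(ph_b, bt_b)
                mod_b = fit_mediation_models(e_b, m_b, y_b, C_b, interaction=interaction)
                pms.append(natural_effects(mod_b, a=a, a_star=a_star).proportion_mediated)
            except (ValueError, KeyError):
                continue
        if len(pms) >= 10:
            result.se_proportion = float(np.std(pms, ddof=1))
    return result
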