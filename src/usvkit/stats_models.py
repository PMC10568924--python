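"""Statistical stage: count and score models over the cohort tables.

* Poisson GLM for received pinnings (log link; treatment and batch fixed).
* OLS for the play asymmetry score.
* Gaussian linear mixed model for per-session 50-kHz counts with rat and
  litter random intercepts (rat nested in litter), day and order
  covariates; ML for fixed-structure comparisons, REML for the reported
  final fit.
* Laplace-approximation Poisson mixed model for 22-kHz counts (no
  maximum-likelihood GLMM fitter exists in the scientific Python stack, so
  the penalized-IRLS inner loop and the profile over variance components
  are implemented here; cross-checked against lme4 in the test suite).
* AICc ranking of candidate fixed structures.
* Variance-component repeatability R = sigma2_term / (sigma2_rat +
  sigma2_litter + sigma2_residual), with parametric-bootstrap CIs; Poisson
  models use the latent (log-link) scale with the distribution-specific
  variance ln(1 + 1/lambda).
* emmeans-style marginal means with Tukey-adjusted pairwise contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelFit",
    "ModelComparison",
    "RepeatabilityResult",
    "MarginalMeans",
    "fit_pinning_glm",
    "fit_asymmetry_lm",
    "fit_usv_lmm",
    "fit_usv22_glmm",
    "fit_lmm",
    "aicc",
    "aicc_rank",
    "repeatability",
    "marginal_means",
    "spearman",
    "contact_rate_model",
    "usv50_candidates",
    "usv22_candidates",
    "rate_candidates",
]


@dataclass
class ModelFit:
    """Uniform view of one fitted model.

    ``vc`` maps variance-component names (``rat``, ``litter``,
    ``residual``) to variances; empty for fixed-effects-only models.
    ``k`` counts fixed effects plus variance components (including the
    residual variance for Gaussian families), the convention used for
    AICc.
    """

    label: str
    family: str  # "gaussian" | "poisson"
    formula: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    n: int
    k: int
    vc: dict = field(default_factory=dict)
    method: str = "ML"
    data: pd.DataFrame | None = None
    response: str | None = None
    rat_col: str | None = None
    litter_col: str | None = None
    design_info: object | None = None
    cov_params: np.ndarray | None = None
    result: object | None = None
    converged: bool = True
    singular: bool = False

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "std_error": self.bse, "p_value": self.pvalues}
        )


@dataclass
class ModelComparison:
    labels: list[str]
    aicc: list[float]
    delta_aicc: list[float]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"model": self.labels, "AICc": self.aicc, "dAICc": self.delta_aicc}
        )

    @property
    def best(self) -> str:
        return self.labels[0]


@dataclass
class RepeatabilityResult:
    term: str
    R: float
    ci_lo: float
    ci_hi: float
    n_boot: int


@dataclass
class MarginalMeans:
    factor: str
    means: pd.DataFrame  # level, mean, ci_lo, ci_hi (response scale)
    contrasts: pd.DataFrame  # pair, estimate (link scale), se, p_tukey


# ---------------------------------------------------------------------------
# Fixed-effects models


def _fixed_design(formula: str, data: pd.DataFrame):
    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    return y.iloc[:, 0].to_numpy(), X


def fit_pinning_glm(play: pd.DataFrame, response: str = "pinnings_received") -> ModelFit:
    """Log-link Poisson GLM for received pinnings.

    The kinematically reduced group (structurally all-zero) is excluded to
    avoid zero inflation; treatment reference is ``control``, batch
    reference the alphabetically first batch.
    """
    df = play[play.treatment != "kinematic_reduced"].copy()
    for col in ("treatment", "batch"):
        if df[col].nunique() < 2:
            raise ValueError(f"degenerate design: predictor {col!r} has one level")
    formula = f"{response} ~ C(treatment, Treatment('control')) + C(batch)"
    res = smf.glm(formula, df, family=sm.families.Poisson()).fit()
    return ModelFit(
        label="pinning_glm",
        family="poisson",
        formula=formula,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        llf=float(res.llf),
        n=int(res.nobs),
        k=len(res.params),
        method="ML",
        data=df,
        response=response,
        design_info=res.model.data.design_info,
        cov_params=np.asarray(res.cov_params()),
        result=res,
    )


def fit_asymmetry_lm(play: pd.DataFrame) -> ModelFit:
    """OLS on the asymmetry score with treatment and batch fixed factors."""
    from .session_metrics import asymmetry_score

    df = play[play.treatment != "kinematic_reduced"].copy()
    if "asymmetry" not in df.columns:
        df["asymmetry"] = [
            asymmetry_score(d, r)
            for d, r in zip(df.pinnings_delivered, df.pinnings_received)
        ]
    formula = "asymmetry ~ C(treatment, Treatment('control')) + C(batch)"
    res = smf.ols(formula, df).fit()
    return ModelFit(
        label="asymmetry_lm",
        family="gaussian",
        formula=formula,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        llf=float(res.llf),
        n=int(res.nobs),
        k=len(res.params) + 1,  # + residual variance
        method="ML",
        data=df,
        response="asymmetry",
        design_info=res.model.data.design_info,
        cov_params=np.asarray(res.cov_params()),
        result=res,
    )


# ---------------------------------------------------------------------------
# Gaussian LMM (rat nested in litter)


def fit_lmm(
    data: pd.DataFrame,
    formula: str,
    rat_col: str = "rat_id",
    litter_col: str = "litter_id",
    reml: bool = False,
    label: str | None = None,
) -> ModelFit:
    """Gaussian LMM with random intercepts for litter and rat-in-litter.

    Implemented with statsmodels MixedLM: the litter is the grouping
    factor carrying a random intercept, and the rat intercept enters as a
    variance component within litters (rats never span litters).
    """
    for col in (rat_col, litter_col):
        if data[col].nunique() < 2:
            raise ValueError(f"random term {col!r} needs >= 2 levels")
    model = smf.mixedlm(
        formula,
        data,
        groups=data[litter_col],
        re_formula="1",
        vc_formula={"rat": f"0 + C({rat_col})"},
    )
    import warnings as _w

    with np.errstate(divide="ignore", invalid="ignore"), _w.catch_warnings():
        _w.simplefilter("ignore")
        res = model.fit(reml=reml, method=["lbfgs", "powell"])
        n_fe = len(res.fe_params)
        vc = {
            "rat": float(res.vcomp[0]),
            "litter": float(np.asarray(res.cov_re)[0, 0]),
            "residual": float(res.scale),
        }
        singular = min(vc["rat"], vc["litter"]) < 1e-8 * max(vc.values())
        bse_fe = res.bse_fe
        pvals = res.pvalues.iloc[:n_fe]
        cov_fe = np.asarray(res.cov_params())[:n_fe, :n_fe]
    return ModelFit(
        label=label or formula,
        family="gaussian",
        formula=formula,
        params=res.fe_params,
        bse=bse_fe,
        pvalues=pvals,
        llf=float(res.llf),
        n=int(res.nobs),
        k=n_fe + 3,  # + rat, litter, residual variances
        vc=vc,
        method="REML" if reml else "ML",
        data=data,
        response=formula.split("~")[0].strip(),
        rat_col=rat_col,
        litter_col=litter_col,
        design_info=res.model.data.design_info,
        cov_params=cov_fe,
        result=res,
        converged=bool(res.converged),
        singular=singular,
    )


USV50_FULL = (
    "n50 ~ C(treatment, Treatment('control')) + C(batch) + day + order"
)


def fit_usv_lmm(
    sessions: pd.DataFrame,
    formula: str = USV50_FULL,
    reml: bool = True,
    **kw,
) -> ModelFit:
    """The per-session 50-kHz count model (Gaussian, rat + litter
    intercepts).  REML by default for the reported coefficient table; use
    ``reml=False`` when comparing fixed structures."""
    return fit_lmm(sessions, formula, reml=reml, **kw)


def usv50_candidates() -> dict[str, str]:
    """Candidate fixed structures for the 50-kHz count model."""
    t = "C(treatment, Treatment('control'))"
    b = "C(batch)"
    return {
        "treatment+batch+days+order": f"n50 ~ {t} + {b} + day + order",
        "treatment+batch+days": f"n50 ~ {t} + {b} + day",
        "treatment+days+order": f"n50 ~ {t} + day + order",
        "batch+days+order": f"n50 ~ {b} + day + order",
        "treatment+batch+order": f"n50 ~ {t} + {b} + order",
        "treatment+batch": f"n50 ~ {t} + {b}",
        "days+order": "n50 ~ day + order",
        "days": "n50 ~ day",
        "intercept": "n50 ~ 1",
    }


def usv22_candidates() -> dict[str, str]:
    t = "C(treatment, Treatment('control'))"
    b = "C(batch)"
    return {
        "batch+days": f"n22 ~ {b} + day",
        "batch+days+order": f"n22 ~ {b} + day + order",
        "treatment+batch+days": f"n22 ~ {t} + {b} + day",
        "treatment+batch+days+order": f"n22 ~ {t} + {b} + day + order",
        "days": "n22 ~ day",
    }


# ---------------------------------------------------------------------------
# Poisson mixed model (Laplace approximation)


def _poisson_laplace_inner(y, X, Zs, vars_, beta0=None, max_iter=200, tol=1e-10):
    """Joint penalized-likelihood mode over (beta, u) for fixed variances.

    ``Zs`` is a list of indicator matrices (one per random term), ``vars_``
    the matching variances.  Returns the mode, the penalized Hessian and
    the Laplace log-likelihood.
    """
    n, p = X.shape
    qs = [Z.shape[1] for Z in Zs]
    W = np.hstack([X] + list(Zs))
    pen = np.concatenate(
        [np.zeros(p)] + [np.full(q, 1.0 / v) for q, v in zip(qs, vars_)]
    )
    coef = np.zeros(W.shape[1])
    if beta0 is not None:
        coef[:p] = beta0
    else:
        coef[0] = np.log(np.mean(y) + 0.5)
    for _ in range(max_iter):
        eta = W @ coef
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        grad = W.T @ (y - mu) - pen * coef
        H = (W.T * mu) @ W
        H[np.diag_indices_from(H)] += pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped Newton
        lam = 1.0
        f0 = np.sum(y * eta - mu) - 0.5 * np.sum(pen * coef**2)
        for _ in range(30):
            new = coef + lam * step
            eta_n = np.clip(W @ new, -30, 30)
            f1 = np.sum(y * eta_n - np.exp(eta_n)) - 0.5 * np.sum(pen * new**2)
            if f1 >= f0 - 1e-12:
                break
            lam *= 0.5
        coef = coef + lam * step
        if np.max(np.abs(lam * step)) < tol:
            break
    eta = np.clip(W @ coef, -30, 30)
    mu = np.exp(eta)
    H = (W.T * mu) @ W
    H[np.diag_indices_from(H)] += pen
    llf = _laplace_llf_at_beta(y, X, Zs, vars_, coef[:p], u0=coef[p:])[0]
    return coef, H, llf


def _laplace_llf_at_beta(y, X, Zs, vars_, beta, u0=None, max_iter=100, tol=1e-11):
    """Laplace marginal log-likelihood for fixed beta: u at its
    conditional mode, plus the Gaussian-integral correction."""
    from scipy.special import gammaln

    Z = np.hstack(Zs)
    q = Z.shape[1]
    dinv = np.concatenate(
        [np.full(Zi.shape[1], 1.0 / v) for Zi, v in zip(Zs, vars_)]
    )
    u = np.zeros(q) if u0 is None else u0.copy()
    off = X @ beta
    for _ in range(max_iter):
        eta = np.clip(off + Z @ u, -30, 30)
        mu = np.exp(eta)
        grad = Z.T @ (y - mu) - dinv * u
        Hu = (Z.T * mu) @ Z
        Hu[np.diag_indices_from(Hu)] += dinv
        try:
            step = np.linalg.solve(Hu, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Hu, grad, rcond=None)[0]
        lam = 1.0
        f0 = np.sum(y * eta - mu) - 0.5 * np.sum(dinv * u**2)
        for _ in range(30):
            un = u + lam * step
            etan = np.clip(off + Z @ un, -30, 30)
            f1 = np.sum(y * etan - np.exp(etan)) - 0.5 * np.sum(dinv * un**2)
            if f1 >= f0 - 1e-12:
                break
            lam *= 0.5
        u = u + lam * step
        if np.max(np.abs(lam * step)) < tol:
            break
    eta = np.clip(off + Z @ u, -30, 30)
    mu = np.exp(eta)
    Hu = (Z.T * mu) @ Z
    Hu[np.diag_indices_from(Hu)] += dinv
    g = np.sum(y * eta - mu - gammaln(y + 1)) - 0.5 * np.sum(dinv * u**2)
    _, logdet_Hu = np.linalg.slogdet(Hu)
    logdet_D = -float(np.sum(np.log(dinv)))
    return g - 0.5 * logdet_D - 0.5 * logdet_Hu, u


def fit_usv22_glmm(
    sessions: pd.DataFrame,
    formula: str = "n22 ~ C(batch) + day",
    rat_col: str = "rat_id",
    litter_col: str = "litter_id",
    label: str | None = None,
) -> ModelFit:
    """Log-link Poisson mixed model with rat and litter random intercepts,
    fitted by Laplace-approximate maximum likelihood."""
    y, Xdf = _fixed_design(formula, sessions)
    X = np.asarray(Xdf)
    Zr = np.asarray(pd.get_dummies(sessions[rat_col]), dtype=float)
    Zl = np.asarray(pd.get_dummies(sessions[litter_col]), dtype=float)
    p = X.shape[1]

    def nll(log_vars):
        vars_ = np.exp(np.clip(log_vars, -12, 6))
        _, _, llf = _poisson_laplace_inner(y, X, [Zr, Zl], vars_)
        return -llf

    opt = optimize.minimize(
        nll, x0=np.log([0.2, 0.05]), method="Nelder-Mead",
        options=dict(xatol=1e-6, fatol=1e-9, maxiter=600),
    )
    # polish: the profile can be flat near a variance boundary
    opt2 = optimize.minimize(
        nll, x0=opt.x, method="Nelder-Mead",
        options=dict(xatol=1e-7, fatol=1e-10, maxiter=400),
    )
    if opt2.fun <= opt.fun:
        opt = opt2
    vars_ = np.exp(np.clip(opt.x, -12, 6))
    coef, H, llf = _poisson_laplace_inner(y, X, [Zr, Zl], vars_)

    # profile beta through the Laplace objective (the joint penalized mode
    # ignores the log-determinant's dependence on beta; lme4 does not)
    u_warm = coef[p:]

    def neg_prof(beta):
        return -_laplace_llf_at_beta(y, X, [Zr, Zl], vars_, beta, u0=u_warm)[0]

    polish = optimize.minimize(neg_prof, x0=coef[:p], method="BFGS",
                               options=dict(gtol=1e-6, maxiter=100))
    if -polish.fun >= llf:
        llf, u_hat = _laplace_llf_at_beta(y, X, [Zr, Zl], vars_, polish.x, u0=u_warm)
        coef = np.concatenate([polish.x, u_hat])
        W = np.hstack([X, Zr, Zl])
        mu_hat = np.exp(np.clip(W @ coef, -30, 30))
        H = (W.T * mu_hat) @ W
        pen = np.concatenate(
            [np.zeros(p), np.full(Zr.shape[1], 1 / vars_[0]), np.full(Zl.shape[1], 1 / vars_[1])]
        )
        H[np.diag_indices_from(H)] += pen

    cov = np.linalg.inv(H)[:p, :p]
    params = pd.Series(coef[:p], index=Xdf.columns)
    bse = pd.Series(np.sqrt(np.diag(cov)), index=Xdf.columns)
    z = params / bse
    pvals = pd.Series(2 * sps.norm.sf(np.abs(z)), index=Xdf.columns)
    vc = {"rat": float(vars_[0]), "litter": float(vars_[1])}
    return ModelFit(
        label=label or formula,
        family="poisson",
        formula=formula,
        params=params,
        bse=bse,
        pvalues=pvals,
        llf=float(llf),
        n=len(y),
        k=p + 2,  # + rat, litter variances
        vc=vc,
        method="ML",
        data=sessions,
        response=formula.split("~")[0].strip(),
        rat_col=rat_col,
        litter_col=litter_col,
        design_info=Xdf.design_info,
        cov_params=cov,
        result=None,
        converged=bool(opt.success),
    )


# ---------------------------------------------------------------------------
# AICc and model ranking


def aicc(fit: ModelFit) -> float:
    """Small-sample Akaike criterion: AIC + 2k(k+1)/(n-k-1)."""
    k, n = fit.k, fit.n
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * fit.llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_rank(fits: Sequence[ModelFit]) -> ModelComparison:
    """Rank candidate fits (same data, ML) by AICc."""
    if not fits:
        raise ValueError("no fits to rank")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError("fits must be on identical data (n differs)")
    vals = [(aicc(f), f.label) for f in fits]
    vals.sort()
    best = vals[0][0]
    return ModelComparison(
        labels=[l for _, l in vals],
        aicc=[a for a, _ in vals],
        delta_aicc=[a - best for a, _ in vals],
    )


# ---------------------------------------------------------------------------
# Repeatability


def _latent_dist_variance(fit: ModelFit) -> float:
    """Distribution-specific variance on the latent log scale for Poisson
    models: ln(1 + 1/lambda_bar), lambda_bar evaluated at the mean fixed
    predictor plus half the summed random variances (lognormal mean)."""
    X = patsy.build_design_matrices([fit.design_info], fit.data)[0]
    eta_bar = float(np.mean(np.asarray(X) @ fit.params.to_numpy()))
    s2 = sum(fit.vc.values())
    lam = np.exp(eta_bar + 0.5 * s2)
    return float(np.log1p(1.0 / lam))


def _point_R(fit: ModelFit, term: str) -> float:
    if fit.family == "gaussian":
        denom = fit.vc["rat"] + fit.vc["litter"] + fit.vc["residual"]
    else:
        denom = fit.vc["rat"] + fit.vc["litter"] + _latent_dist_variance(fit)
    if denom <= 0:
        raise ValueError("R undefined: all variance components are zero")
    return fit.vc[term] / denom


def _simulate_response(fit: ModelFit, rng: np.random.Generator) -> np.ndarray:
    """Draw one parametric-bootstrap response from the fitted model."""
    data = fit.data
    X = np.asarray(patsy.build_design_matrices([fit.design_info], data)[0])
    eta = X @ fit.params.to_numpy()
    rats = data[fit.rat_col].to_numpy()
    lits = data[fit.litter_col].to_numpy()
    u_r = dict(zip(*(lvls := np.unique(rats),
                     rng.normal(0, np.sqrt(fit.vc["rat"]), lvls.size))))
    u_l = dict(zip(*(lvls := np.unique(lits),
                     rng.normal(0, np.sqrt(fit.vc["litter"]), lvls.size))))
    eta = eta + np.vectorize(u_r.get)(rats) + np.vectorize(u_l.get)(lits)
    if fit.family == "gaussian":
        return eta + rng.normal(0, np.sqrt(fit.vc["residual"]), eta.size)
    return rng.poisson(np.exp(np.clip(eta, -30, 30))).astype(float)


def repeatability(
    fit: ModelFit,
    term: str = "rat",
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> RepeatabilityResult:
    """Variance-component repeatability with parametric-bootstrap CI.

    R = sigma2_term / (sigma2_rat + sigma2_litter + sigma2_residual) for
    Gaussian fits; Poisson fits use the latent log scale with the
    distribution-specific variance in the denominator.  The bootstrap
    simulates from the fitted model, refits, and takes percentile limits.
    """
    if term not in fit.vc:
        raise ValueError(f"{term!r} is not a random term of this fit")
    R = _point_R(fit, term)
    if n_boot <= 0:
        return RepeatabilityResult(term, R, float("nan"), float("nan"), 0)
    rng = np.random.default_rng(seed)
    draws = []
    reml = fit.method == "REML"
    for _ in range(n_boot):
        sim = fit.data.copy()
        sim[fit.response] = _simulate_response(fit, rng)
        try:
            if fit.family == "gaussian":
                refit = fit_lmm(
                    sim, fit.formula, rat_col=fit.rat_col,
                    litter_col=fit.litter_col, reml=reml,
                )
            else:
                refit = fit_usv22_glmm(
                    sim, fit.formula, rat_col=fit.rat_col, litter_col=fit.litter_col
                )
            draws.append(_point_R(refit, term))
        except Exception:
            continue
    draws = np.asarray(draws)
    a = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(draws, [a, 1.0 - a]) if draws.size else (np.nan, np.nan)
    return RepeatabilityResult(term, R, float(lo), float(hi), int(draws.size))


# ---------------------------------------------------------------------------
# Marginal means (emmeans-style)


def _factor_column(design_info, data: pd.DataFrame, factor: str) -> str:
    for col in data.columns:
        if col == factor:
            return col
    raise ValueError(f"factor {factor!r} not found in model data")


def marginal_means(
    fit: ModelFit,
    factor: str,
    covariates_at_means: bool = True,
    ci_level: float = 0.95,
) -> MarginalMeans:
    """Estimated marginal means of ``factor`` with Tukey-adjusted pairwise
    contrasts.

    Levels of the target factor are crossed with all levels of the other
    categorical model terms (equal weights); numeric covariates sit at
    their observed means.  Means are averaged on the link scale and
    back-transformed for Poisson fits; CIs use the normal approximation on
    the link scale.
    """
    data = fit.data
    _factor_column(fit.design_info, data, factor)
    levels = list(pd.unique(data[factor]))
    levels.sort()
    other_cats = [
        c
        for c in data.columns
        if c != factor
        and (data[c].dtype == object or isinstance(data[c].dtype, pd.CategoricalDtype))
        and f"C({c}" in fit.formula
    ]
    nums = [
        c
        for c in data.columns
        if c != factor
        and np.issubdtype(np.asarray(data[c]).dtype, np.number)
        and c in fit.formula
        and c != fit.response
    ]
    grids = []
    for lev in levels:
        combos = [{}]
        for oc in other_cats:
            combos = [
                {**cb, oc: v} for cb in combos for v in sorted(pd.unique(data[oc]))
            ]
        rows = []
        for cb in combos:
            row = {factor: lev, **cb}
            for nc in nums:
                row[nc] = float(data[nc].mean()) if covariates_at_means else 0.0
            rows.append(row)
        grids.append(pd.DataFrame(rows))

    beta = fit.params.to_numpy()
    cov = fit.cov_params
    ests, ses = [], []
    Ls = []
    for g in grids:
        Xg = np.asarray(patsy.build_design_matrices([fit.design_info], g)[0])
        L = Xg.mean(axis=0)
        Ls.append(L)
        ests.append(float(L @ beta))
        ses.append(float(np.sqrt(L @ cov @ L)))
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    inv = np.exp if fit.family == "poisson" else (lambda v: v)
    means = pd.DataFrame(
        {
            "level": levels,
            "mean": [inv(e) for e in ests],
            "ci_lo": [inv(e - z * s) for e, s in zip(ests, ses)],
            "ci_hi": [inv(e + z * s) for e, s in zip(ests, ses)],
        }
    )
    # Tukey pairwise on the link scale
    kk = len(levels)
    dfree = max(fit.n - fit.k, 2)
    rows = []
    for i in range(kk):
        for j in range(i + 1, kk):
            L = Ls[i] - Ls[j]
            est = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            q = abs(est) / se * np.sqrt(2.0) if se > 0 else np.inf
            p = float(sps.studentized_range.sf(q, kk, dfree)) if kk > 1 else np.nan
            rows.append(
                dict(pair=f"{levels[i]} - {levels[j]}", estimate=est, se=se, p_tukey=p)
            )
    return MarginalMeans(factor=factor, means=means, contrasts=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Correlation and the contact-period rate model


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for constant input")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


RATE_FULL = (
    "rate_per_s ~ C(period_type, Treatment('none'))"
    " + C(treatment, Treatment('control'))"
)


def rate_candidates() -> dict[str, str]:
    pt = "C(period_type, Treatment('none'))"
    t = "C(treatment, Treatment('control'))"
    return {
        "contact+treatment": f"rate_per_s ~ {pt} + {t}",
        "contact+treatment+duration": f"rate_per_s ~ {pt} + {t} + total_duration_s",
        "contact*treatment+duration": f"rate_per_s ~ {pt} * {t} + total_duration_s",
        "contact*treatment": f"rate_per_s ~ {pt} * {t}",
        "contact+treatment+days": f"rate_per_s ~ {pt} + {t} + day",
    }


def contact_rate_model(
    rates: pd.DataFrame,
    formula: str = RATE_FULL,
    reml: bool = True,
    **kw,
) -> ModelFit:
    """Gaussian LMM for per-contact-period emission rates (one row per
    session x period type), rat and litter random intercepts."""
    return fit_lmm(rates, formula, reml=reml, **kw)
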