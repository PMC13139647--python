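"""Gamma log-link mixed models of stand productivity on CSFI.

The model for subplot productivity y (AWP, cm^3 yr^-1, strictly
positive) in plot g is

    y_i | b_g ~ Gamma(shape = nu, mean = mu_i)
    log mu_i  = x_i' beta + b_g,        b_g ~ Normal(0, sigma_plot^2)

with x_i holding an intercept, the CSFI of one canopy definition and
optionally the mixture-type factor and its interaction with CSFI. The
plot random intercept absorbs the nesting of four subplots per plot.

Estimation is maximum likelihood with a Laplace approximation to the
random-intercept integral. For this model the per-group conditional
log-density is strictly concave in b_g with closed-form first and
second derivatives, so the inner mode is found by a vectorised Newton
iteration; the outer optimisation over (beta, log sigma, log nu) uses
L-BFGS-B. Wald standard errors come from the numerically differentiated
Hessian of the marginal negative log-likelihood.

Marginal R^2 (variance explained by fixed effects on the link scale)
uses the gamma observation-level variance trigamma(nu):

    R2m = var(X beta) / (var(X beta) + sigma_plot^2 + trigamma(nu))

A lognormal-approximation variant (log(1 + 1/nu)) is available via
``resid_variance="lognormal"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "GammaGLMMFit",
    "fit_gamma_glmm",
    "fit_glmm",
    "marginal_r2",
    "definition_comparison",
    "ComparisonReport",
]

_B_CLIP = 30.0
_INNER_TOL = 1e-11
_INNER_MAX_ITER = 200
LOG_SIGMA_BOUNDS = (np.log(1e-8), np.log(1e2))
LOG_SHAPE_BOUNDS = (np.log(1e-4), np.log(1e6))


@dataclass
class GammaGLMMFit:
    """Result of one gamma log-link mixed-model fit."""

    term_names: list[str]
    coef: np.ndarray          # link-scale fixed-effect estimates
    se: np.ndarray            # Wald standard errors
    zvalues: np.ndarray
    pvalues: np.ndarray
    sigma_plot: float         # random-intercept SD
    shape: float              # gamma shape nu
    loglik: float
    converged: bool
    message: str
    n_obs: int
    n_groups: int
    var_fixed: float          # variance of the fixed-effect linear predictor
    ranef: Optional[np.ndarray] = None   # conditional modes b_hat per group
    group_labels: Optional[np.ndarray] = None
    resid_variance: str = "trigamma"

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.term_names,
            "estimate": self.coef,
            "se": self.se,
            "z": self.zvalues,
            "p": self.pvalues,
        })

    def __getitem__(self, term: str) -> dict[str, float]:
        i = self.term_names.index(term)
        return {"estimate": self.coef[i], "se": self.se[i],
                "z": self.zvalues[i], "p": self.pvalues[i]}


def _solve_modes(b: np.ndarray, nu: float, sigma2: float, A: np.ndarray,
                 n_g: np.ndarray) -> np.ndarray:
    """Newton solve of the per-group conditional modes.

    Root of f'(b) = nu * (A * exp(-b) - n_g) - b / sigma2, which is
    strictly decreasing and convex in b, so damped Newton converges.
    """
    scale = max(1.0, float(nu * n_g.max()))
    for _ in range(_INNER_MAX_ITER):
        e = np.exp(-np.clip(b, -_B_CLIP, _B_CLIP))
        g1 = nu * (A * e - n_g) - b / sigma2
        if np.max(np.abs(g1)) < _INNER_TOL * scale:
            break
        g2 = -nu * A * e - 1.0 / sigma2
        step = np.clip(-g1 / g2, -5.0, 5.0)
        b = np.clip(b + step, -_B_CLIP, _B_CLIP)
    return b


def _marginal_nll(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                  codes: np.ndarray, n_groups: int, logy_sum: float,
                  return_modes: bool = False):
    """Laplace-approximate negative marginal log-likelihood."""
    p = X.shape[1]
    beta = theta[:p]
    sigma = np.exp(theta[p])
    nu = np.exp(theta[p + 1])
    sigma2 = sigma * sigma

    eta = X @ beta
    eta = np.clip(eta, -300, 300)
    w = y * np.exp(-eta)                      # y_i * exp(-eta_i)
    A = np.bincount(codes, weights=w, minlength=n_groups)
    n_g = np.bincount(codes, minlength=n_groups).astype(float)

    b = _solve_modes(np.zeros(n_groups), nu, sigma2, A, n_g)
    e = np.exp(-np.clip(b, -_B_CLIP, _B_CLIP))

    n = y.shape[0]
    ll = (
        n * (nu * np.log(nu) - special.gammaln(nu))
        + (nu - 1.0) * logy_sum
        - nu * float(eta.sum())
        - nu * float((n_g * b).sum())
        - nu * float((A * e).sum())
        - float((b * b).sum()) / (2.0 * sigma2)
        - 0.5 * n_groups * np.log(sigma2)
        - 0.5 * float(np.log(nu * A * e + 1.0 / sigma2).sum())
    )
    if return_modes:
        return -ll, b
    return -ll


def _numeric_hessian(fun, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian (small parameter counts only)."""
    k = theta.size
    h = rel_step * np.maximum(1.0, np.abs(theta))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = fun(theta + ei + ej)
            fpm = fun(theta + ei - ej)
            fmp = fun(theta - ei + ej)
            fmm = fun(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_gamma_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: Sequence,
    term_names: Optional[Sequence[str]] = None,
    resid_variance: str = "trigamma",
    start_sigma: float = 0.2,
    fixed_sigma: Optional[float] = None,
) -> GammaGLMMFit:
    """Fit the gamma log-link random-intercept model by Laplace ML.

    Parameters
    ----------
    y : strictly positive response vector.
    X : (n, p) fixed-effects design matrix (include the intercept).
    groups : length-n group labels defining the random intercept.
    term_names : names for the columns of X.
    resid_variance : "trigamma" or "lognormal"; only affects marginal R^2.
    fixed_sigma : pin the random-intercept SD at a known value instead
        of estimating it (0 collapses the model to a fixed-effects
        gamma GLM — the boundary case of the Laplace likelihood).

    A rank-deficient design or optimiser failure yields a flagged
    (``converged=False``) fit with NaN inference, never an exception.
    Non-positive responses raise ``ValueError``: they must be filtered
    upstream (the gamma likelihood is undefined there).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) aligned with y")
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        raise ValueError("response must be strictly positive and finite "
                         "(filter non-positive AWP rows upstream)")
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    n, p = X.shape
    n_groups = labels.size
    names = list(term_names) if term_names is not None else [f"x{i}" for i in range(p)]

    def _flagged(msg: str) -> GammaGLMMFit:
        nan = np.full(p, np.nan)
        return GammaGLMMFit(names, nan, nan.copy(), nan.copy(), nan.copy(),
                            float("nan"), float("nan"), float("nan"), False, msg,
                            n, n_groups, float("nan"),
                            resid_variance=resid_variance)

    if n_groups < 2:
        return _flagged("fewer than 2 groups")
    if n < p + 2:
        return _flagged("too few observations for the requested terms")
    if np.linalg.matrix_rank(X) < p:
        return _flagged("rank-deficient design (a predictor is constant or collinear)")

    beta0, nu0 = _glm_start(y, X)
    logy_sum = float(np.log(y).sum())
    args = (y, X, codes, n_groups, logy_sum)

    if fixed_sigma is None:
        theta0 = np.concatenate([beta0, [np.log(max(start_sigma, 1e-6))],
                                 [np.log(np.clip(nu0, 1e-3, 1e5))]])
        objective = _marginal_nll
        expand = lambda t: t
        bounds = [(None, None)] * p + [LOG_SIGMA_BOUNDS, LOG_SHAPE_BOUNDS]
    else:
        if fixed_sigma < 0:
            raise ValueError("fixed_sigma must be non-negative")
        log_sigma = np.log(max(fixed_sigma, np.exp(LOG_SIGMA_BOUNDS[0])))
        theta0 = np.concatenate([beta0, [np.log(np.clip(nu0, 1e-3, 1e5))]])
        expand = lambda t: np.concatenate([t[:p], [log_sigma], t[p:]])
        objective = lambda t, *a: _marginal_nll(expand(t), *a)
        bounds = [(None, None)] * p + [LOG_SHAPE_BOUNDS]

    res = optimize.minimize(
        objective, theta0, args=args, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    theta = expand(res.x)
    nll, modes = _marginal_nll(theta, *args, return_modes=True)
    beta = theta[:p]
    sigma = float(np.exp(theta[p]))
    nu = float(np.exp(theta[p + 1]))

    H = _numeric_hessian(lambda t: objective(t, *args), res.x)
    cov = _safe_inverse(H)
    if cov is None:
        se = np.full(p, np.nan)
        ok = False
        msg = "Hessian not invertible"
    else:
        var = np.diag(cov)[:p]
        se = np.sqrt(np.where(var > 0, var, np.nan))
        ok = bool(res.success) and np.all(np.isfinite(se))
        msg = str(res.message)
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    eta_fixed = X @ beta
    var_fixed = float(np.var(eta_fixed))
    return GammaGLMMFit(
        term_names=names, coef=beta, se=se, zvalues=z, pvalues=pvals,
        sigma_plot=sigma, shape=nu, loglik=-float(nll), converged=ok,
        message=msg, n_obs=n, n_groups=n_groups, var_fixed=var_fixed,
        ranef=modes, group_labels=labels, resid_variance=resid_variance,
    )


def _glm_start(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Starting values from a fixed-effects gamma GLM (moment fallback)."""
    try:
        import statsmodels.api as sm
        glm = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
        fit = glm.fit()
        nu0 = 1.0 / max(float(fit.scale), 1e-8)
        return np.asarray(fit.params, dtype=float), nu0
    except Exception:
        beta = np.zeros(X.shape[1])
        # assume the first column is the intercept
        beta[0] = np.log(float(np.mean(y)))
        cv2 = float(np.var(y) / np.mean(y) ** 2)
        return beta, 1.0 / max(cv2, 1e-3)


def _safe_inverse(H: np.ndarray) -> Optional[np.ndarray]:
    try:
        cov = np.linalg.inv(H)
        if np.all(np.isfinite(cov)):
            return cov
    except np.linalg.LinAlgError:
        pass
    try:
        return np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        return None


def marginal_r2(fit: GammaGLMMFit) -> float:
    """Nakagawa-style marginal R^2 of a converged fit.

    Fraction of link-scale variance attributable to fixed effects:
    ``var_f / (var_f + sigma_plot^2 + var_resid)`` with the
    observation-level variance ``trigamma(nu)`` (or ``log(1 + 1/nu)``
    under the lognormal approximation).
    """
    if not fit.converged or not np.isfinite(fit.var_fixed):
        raise ValueError("marginal R^2 is undefined for a non-converged fit")
    if fit.resid_variance == "trigamma":
        var_resid = float(special.polygamma(1, fit.shape))
    elif fit.resid_variance == "lognormal":
        var_resid = float(np.log1p(1.0 / fit.shape))
    else:
        raise ValueError("resid_variance must be 'trigamma' or 'lognormal'")
    denom = fit.var_fixed + fit.sigma_plot ** 2 + var_resid
    return fit.var_fixed / denom


def _design(table: pd.DataFrame, csfi_col: str, include_mixture: bool,
            include_interaction: bool) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table)), table[csfi_col].to_numpy(dtype=float)]
    names = ["(Intercept)", "CSFI"]
    if include_mixture or include_interaction:
        mix = (table["mixture_type"].astype(str) == "mixture").to_numpy(dtype=float)
        cols.append(mix)
        names.append("mixture")
        if include_interaction:
            cols.append(mix * table[csfi_col].to_numpy(dtype=float))
            names.append("CSFI:mixture")
    return np.column_stack(cols), names


def fit_glmm(
    table: pd.DataFrame,
    csfi_col: str = "csfi",
    response_col: str = "awp_cm3_yr",
    group_col: str = "plot_id",
    include_mixture: bool = False,
    include_interaction: bool = False,
    resid_variance: str = "trigamma",
    fixed_sigma: Optional[float] = None,
) -> GammaGLMMFit:
    """Fit AWP ~ CSFI (+ mixture + CSFI:mixture) with a plot random
    intercept on a joined CSFI x AWP table."""
    X, names = _design(table, csfi_col, include_mixture, include_interaction)
    return fit_gamma_glmm(
        table[response_col].to_numpy(dtype=float), X,
        table[group_col].to_numpy(), term_names=names,
        resid_variance=resid_variance, fixed_sigma=fixed_sigma,
    )


@dataclass
class ComparisonReport:
    """Per-definition, per-stratum CSFI effects plus interaction tests."""

    coefficients: pd.DataFrame   # definition, stratum, term, estimate, se, p, marginal_r2, ...
    interactions: pd.DataFrame   # definition, p_interaction, converged

    def to_csv(self, coef_path, interaction_path) -> None:
        self.coefficients.to_csv(coef_path, index=False)
        self.interactions.to_csv(interaction_path, index=False)


STRATA = ("across", "mixtures", "monocultures")


def definition_comparison(
    tables: dict[str, pd.DataFrame],
    csfi_col: str = "csfi",
    response_col: str = "awp_cm3_yr",
    resid_variance: str = "trigamma",
) -> ComparisonReport:
    """Fit the CSFI-AWP model for every canopy definition and stratum.

    ``tables`` maps definition name to a joined table with columns
    ``csfi``, ``awp_cm3_yr``, ``plot_id``, ``mixture_type`` (rows with
    invalid CSFI or non-positive AWP already removed). For each
    definition three models are fitted: across all subplots, mixtures
    only, monocultures only (each AWP ~ CSFI with a plot random
    intercept), plus an across-model with the CSFI x mixture-type
    interaction whose interaction p-value is reported separately.
    Strata with fewer than 2 plots yield flagged rows.
    """
    coef_rows = []
    inter_rows = []
    for definition, tab in tables.items():
        for stratum in STRATA:
            if stratum == "across":
                sub = tab
            elif stratum == "mixtures":
                sub = tab[tab["mixture_type"].astype(str) == "mixture"]
            else:
                sub = tab[tab["mixture_type"].astype(str) == "monoculture"]
            row = {"definition": definition, "stratum": stratum, "term": "CSFI"}
            if sub["plot_id"].nunique() < 2:
                row.update({"estimate": np.nan, "se": np.nan, "p": np.nan,
                            "marginal_r2": np.nan, "sigma_plot": np.nan,
                            "shape": np.nan, "n": len(sub), "converged": False,
                            "message": "fewer than 2 plots in stratum"})
            else:
                fit = fit_glmm(sub, csfi_col=csfi_col, response_col=response_col,
                               resid_variance=resid_variance)
                eff = fit["CSFI"] if fit.converged else {
                    "estimate": np.nan, "se": np.nan, "p": np.nan}
                row.update({
                    "estimate": eff["estimate"], "se": eff["se"], "p": eff["p"],
                    "marginal_r2": marginal_r2(fit) if fit.converged else np.nan,
                    "sigma_plot": fit.sigma_plot, "shape": fit.shape,
                    "n": fit.n_obs, "converged": fit.converged,
                    "message": fit.message,
                })
            coef_rows.append(row)

        if tab["mixture_type"].astype(str).nunique() < 2:
            inter_rows.append({"definition": definition, "p_interaction": np.nan,
                               "converged": False})
        else:
            ifit = fit_glmm(tab, csfi_col=csfi_col, response_col=response_col,
                            include_mixture=True, include_interaction=True,
                            resid_variance=resid_variance)
            p_int = ifit["CSFI:mixture"]["p"] if ifit.converged else np.nan
            inter_rows.append({"definition": definition, "p_interaction": p_int,
                               "converged": ifit.converged})
    return ComparisonReport(pd.DataFrame(coef_rows), pd.DataFrame(inter_rows))
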