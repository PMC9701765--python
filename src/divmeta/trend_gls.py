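"""Effect-size trends over the number of added genotypes (heteroscedastic GLS).

The response is the standardized mean difference, the predictor the base-2
logarithm of the number of plant genotypes added over the single-genotype
control.  Errors follow an exponential variance function of the fitted
values,

.. math::

    \\mathrm{Var}(\\varepsilon_i) = \\sigma^2 \\exp(2\\delta\\,\\hat\\mu_i),

estimated by iterating a profile likelihood over ``delta`` (the variance
covariate being the current fitted values) to convergence.  At ``delta = 0``
the fit reduces exactly to OLS.  Slope inference uses t with
``df = n - 2``; residual variance for standard errors is the REML-type
``RSS_w / (n - p)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


class GlsConvergenceError(RuntimeError):
    pass


class GlsDesignError(ValueError):
    pass


def log_genotypes(n_genotypes_added: int | np.ndarray) -> float | np.ndarray:
    """log2 of the number of added genotypes; n must be >= 1."""
    arr = np.asarray(n_genotypes_added, float)
    if np.any(arr < 1):
        raise ValueError("number of added genotypes must be >= 1")
    out = np.log2(arr)
    return float(out) if out.ndim == 0 else out


@dataclass
class GlsFit:
    """GLS fit with exponential variance function of the fitted values."""

    beta: np.ndarray           # (intercept, slope)
    vcov_beta: np.ndarray
    delta: float
    sigma2: float
    df_resid: int
    t_slope: float
    p_slope: float
    loglik: float
    x: np.ndarray
    fitted: np.ndarray
    group: str | None = None

    @property
    def slope(self) -> float:
        return float(self.beta[1])


def _wls(X, y, w):
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ y)
    return beta, XtWX


def _profile_ll(delta, X, y, mu):
    """ML log-likelihood profiled over beta and sigma2 for fixed delta, mu."""
    w = np.exp(-2.0 * delta * mu)
    beta, _ = _wls(X, y, w)
    r = y - X @ beta
    n = len(y)
    sigma2 = float(np.sum(w * r * r) / n)
    if sigma2 <= 0:
        return -np.inf, beta, sigma2
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - delta * float(np.sum(mu))
    return ll, beta, sigma2


def fit_gls_varexp(
    x: np.ndarray,
    y: np.ndarray,
    delta: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    group: str | None = None,
) -> GlsFit:
    """Fit ``y = b0 + b1 x`` with Var(eps_i) = sigma^2 exp(2 delta mu_i).

    Parameters
    ----------
    x, y
        Predictor (log2 added genotypes) and effect sizes; length >= 4,
        ``x`` not constant.
    delta
        If given, the variance parameter is held fixed (``delta=0`` gives
        OLS exactly); otherwise it is estimated by iterated profile
        likelihood with the fitted values as variance covariate.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise GlsDesignError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise GlsDesignError("x is constant")
    X = np.column_stack([np.ones_like(x), x])
    n, p = X.shape

    beta_ols, _ = _wls(X, y, np.ones(n))

    def solve_at(d: float) -> tuple[float, np.ndarray]:
        """Self-consistent beta for fixed delta (damped fixed point on the
        variance covariate = fitted values), returning the profiled ll."""
        beta = beta_ols.copy()
        ll_prev = -np.inf
        for it in range(max_iter):
            ll, beta_new, _ = _profile_ll(d, X, y, X @ beta)
            if not np.all(np.isfinite(beta_new)):
                raise GlsConvergenceError("diverged at delta=%g" % d)
            step = 1.0 if it < 10 else 0.5
            beta = beta + step * (beta_new - beta)
            if abs(ll - ll_prev) < tol:
                return ll, beta
            ll_prev = ll
        if abs(ll - ll_prev) > 1e-4:
            raise GlsConvergenceError(
                "variance-function iteration did not converge")
        return ll, beta

    if delta is not None:
        delta_hat = float(delta)
        ll, beta = solve_at(delta_hat)
    else:
        res = optimize.minimize_scalar(
            lambda d: -solve_at(d)[0],
            bounds=(-20.0, 20.0), method="bounded",
            options={"xatol": 1e-9})
        delta_hat = float(res.x)
        ll, beta = solve_at(delta_hat)
    mu = X @ beta
    w = np.exp(-2.0 * delta_hat * mu)
    beta, XtWX = _wls(X, y, w)
    r = y - X @ beta
    sigma2 = float(np.sum(w * r * r) / (n - p))
    vcov = sigma2 * np.linalg.inv(XtWX)
    t_slope = float(beta[1] / np.sqrt(vcov[1, 1]))
    df = n - p
    return GlsFit(
        beta=beta, vcov_beta=vcov, delta=delta_hat, sigma2=sigma2,
        df_resid=df, t_slope=t_slope,
        p_slope=float(2 * stats.t.sf(abs(t_slope), df)),
        loglik=float(ll), x=x, fitted=X @ beta, group=group,
    )


def fit_trends(
    effects: pd.DataFrame,
    by_group: bool = True,
) -> dict[str, GlsFit]:
    """Fit the genotype-number trend pooled and (optionally) per trophic group.

    Expects columns ``g``, ``n_genotypes_added`` and ``trophic_group``.
    Groups with fewer than 4 observations or constant predictor are skipped.
    """
    out: dict[str, GlsFit] = {}
    x_all = log_genotypes(effects["n_genotypes_added"].to_numpy())
    out["pooled"] = fit_gls_varexp(x_all, effects["g"].to_numpy(), group="pooled")
    if by_group:
        for grp, sub in effects.groupby("trophic_group"):
            x = log_genotypes(sub["n_genotypes_added"].to_numpy())
            if len(x) < 4 or np.ptp(x) == 0:
                continue
            out[str(grp)] = fit_gls_varexp(x, sub["g"].to_numpy(), group=str(grp))
    return out


def predict_with_band(fit: GlsFit, x_grid: np.ndarray,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Marginal predictions with pointwise CI from the coefficient covariance.

    Grid points outside the observed x range are flagged (``extrapolated``)
    rather than refused.
    """
    x_grid = np.asarray(x_grid, float)
    Xg = np.column_stack([np.ones_like(x_grid), x_grid])
    fit_vals = Xg @ fit.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, fit.vcov_beta, Xg))
    tcrit = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    return pd.DataFrame({
        "x": x_grid,
        "fit": fit_vals,
        "lo": fit_vals - tcrit * se,
        "hi": fit_vals + tcrit * se,
        "extrapolated": (x_grid < fit.x.min()) | (x_grid > fit.x.max()),
    })
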