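"""Publication-bias diagnostics: residual regression test and fail-safe N.

The regression test follows the residual-based approach for mixed-effects
meta-regression: the fitted model is re-estimated with each observation's
sampling variance appended as an additional moderator; a significant
coefficient indicates small-study asymmetry (funnel-plot asymmetry within
the multilevel model).  The Rosenthal fail-safe number is the count of
unpublished null results needed to lift the combined one-tailed significance
test above alpha:

.. math::

    N = \\max\\Bigl(0, \\Bigl\\lceil \\frac{(\\sum_i z_i)^2}{z_\\alpha^2} - k
        \\Bigr\\rceil\\Bigr).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .meta_regression import DesignError, MetaFit, build_design, fit_meta

__all__ = ["BiasReport", "regression_bias_test", "failsafe_rosenthal",
           "z_from_effects"]


@dataclass(frozen=True)
class BiasReport:
    slope_v: float
    t_v: float
    p_v: float
    failsafe_n: int
    alpha_one_tailed: float = 0.05


def regression_bias_test(
    data: pd.DataFrame,
    moderators: Sequence[str] = ("trophic_group",),
    intercept: bool = False,
    components: Sequence[str] = ("tau2_study", "tau2_obs"),
    variance_moderator: str = "v",
    use_se: bool = False,
    **fit_kwargs,
) -> tuple[float, float, float, MetaFit]:
    """Refit the meta-regression with sampling variance as extra moderator.

    Returns ``(slope_v, t_v, p_v, fit)``.  ``use_se=True`` substitutes the
    standard error sqrt(v) for the variance (Egger's classical covariate).
    A variance column collinear with the existing design raises
    :class:`~divmeta.meta_regression.DesignError`.
    """
    data = data.reset_index(drop=True).copy()
    col = "_bias_mod"
    vals = data[variance_moderator].to_numpy(float)
    data[col] = np.sqrt(vals) if use_se else vals
    X0, _ = build_design(data, moderators, intercept=intercept)
    resid = data[col].to_numpy() - X0 @ np.linalg.lstsq(
        X0, data[col].to_numpy(), rcond=None)[0]
    if float(np.abs(resid).max()) < 1e-10:
        raise DesignError("variance moderator is collinear with the design")
    fit = fit_meta(data, moderators=[*moderators, col], intercept=intercept,
                   components=components, **fit_kwargs)
    slope = float(fit.beta[col])
    t = slope / float(fit.se[col])
    p = float(2 * stats.t.sf(abs(t), fit.df_resid))
    return slope, float(t), p, fit


def z_from_effects(g: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Per-observation z scores g / sqrt(v), signs kept as reported."""
    return np.asarray(g, float) / np.sqrt(np.asarray(v, float))


def failsafe_rosenthal(z: Sequence[float], alpha: float = 0.05) -> int:
    """Rosenthal's fail-safe number from one-tailed z scores.

    The number of hidden zero-effect studies that would push the Stouffer
    combined test above the one-tailed ``alpha``.
    """
    z = np.asarray(list(z), float)
    if z.size == 0:
        raise ValueError("need at least one z score")
    z_alpha = stats.norm.isf(alpha)
    n = np.ceil(float(np.sum(z)) ** 2 / z_alpha**2 - z.size)
    return int(max(0, n))


def bias_report(
    data: pd.DataFrame,
    moderators: Sequence[str] = ("trophic_group",),
    alpha_one_tailed: float = 0.05,
    **kwargs,
) -> BiasReport:
    """Regression test plus fail-safe N for one model specification."""
    slope, t, p, _ = regression_bias_test(data, moderators=moderators, **kwargs)
    z = z_from_effects(data["g"].to_numpy(), data["v"].to_numpy())
    return BiasReport(slope_v=slope, t_v=t, p_v=p,
                      failsafe_n=failsafe_rosenthal(z, alpha_one_tailed),
                      alpha_one_tailed=alpha_one_tailed)
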