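"""Standardized mean difference (Hedges' g) with unbiased sampling variance.

For observation *i* with treatment/control means ``M_t, M_c``, SDs
``sd_t, sd_c`` and group sizes ``n_t, n_c``:

.. math::

    s_p = \\sqrt{\\frac{(n_t-1)sd_t^2 + (n_c-1)sd_c^2}{n_t+n_c-2}}, \\qquad
    d = (M_t - M_c)/s_p

with pooled degrees of freedom ``m = n_t + n_c - 2``.  The small-sample bias
correction is ``J = 1 - 3/(4m - 1)`` and ``g = J d``.  The sampling variance
uses Hedges' (1983) unbiased estimator

.. math::

    v = \\frac{n_t+n_c}{n_t n_c} + \\Bigl(1 - \\frac{m-2}{m J^2}\\Bigr) g^2,

i.e. the "UB" variance type of standard meta-analysis software, audited
constant by constant against that software in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataio import ObservationRecord


class DegenerateInputError(ValueError):
    """Both arms report zero SD: the standardized difference is undefined."""


@dataclass(frozen=True)
class EffectSize:
    """Bias-corrected SMD ``g``, sampling variance ``v``, pooled df ``m``,
    and the correction factor ``j`` in (0, 1)."""

    g: float
    v: float
    m: int
    j: float


def pooled_sd(sd_treat: float, sd_ctrl: float,
              n_treat: int, n_ctrl: int) -> float:
    """Pooled standard deviation of the two arms (df-weighted)."""
    m = n_treat + n_ctrl - 2
    if m < 1:
        raise ValueError("pooled df must be >= 1")
    if sd_treat == 0 and sd_ctrl == 0:
        raise DegenerateInputError("both SDs are zero")
    num = (n_treat - 1) * sd_treat**2 + (n_ctrl - 1) * sd_ctrl**2
    return float(np.sqrt(num / m))


def bias_correction(m: int) -> float:
    """Small-sample correction J = 1 - 3/(4m - 1)."""
    if m < 2:
        raise ValueError("m must be >= 2")
    return 1.0 - 3.0 / (4.0 * m - 1.0)


def smd(record: ObservationRecord) -> EffectSize:
    """Hedges' g and its unbiased sampling variance for one observation."""
    return smd_from_stats(
        record.mean_treat, record.mean_ctrl,
        record.sd_treat, record.sd_ctrl,
        record.n_treat, record.n_ctrl,
    )


def smd_from_stats(mean_treat: float, mean_ctrl: float,
                   sd_treat: float, sd_ctrl: float,
                   n_treat: int, n_ctrl: int) -> EffectSize:
    sp = pooled_sd(sd_treat, sd_ctrl, n_treat, n_ctrl)
    m = n_treat + n_ctrl - 2
    j = bias_correction(m)
    d = (mean_treat - mean_ctrl) / sp
    g = j * d
    v = (n_treat + n_ctrl) / (n_treat * n_ctrl) \
        + (1.0 - (m - 2.0) / (m * j * j)) * g * g
    return EffectSize(g=float(g), v=float(v), m=m, j=float(j))


def swap_arms(record: ObservationRecord) -> ObservationRecord:
    """Exchange treatment and control summaries (antisymmetry helper)."""
    return replace(
        record,
        mean_treat=record.mean_ctrl, mean_ctrl=record.mean_treat,
        sd_treat=record.sd_ctrl, sd_ctrl=record.sd_treat,
        n_treat=record.n_ctrl, n_ctrl=record.n_treat,
    )


def add_effect_sizes(obs: pd.DataFrame) -> pd.DataFrame:
    """Augment an observation table with columns ``g, v, m, j`` (vectorized)."""
    nt = obs["n_treat"].to_numpy(float)
    nc = obs["n_ctrl"].to_numpy(float)
    st = obs["sd_treat"].to_numpy(float)
    sc = obs["sd_ctrl"].to_numpy(float)
    m = nt + nc - 2
    sp2 = ((nt - 1) * st**2 + (nc - 1) * sc**2) / m
    if np.any(sp2 <= 0):
        raise DegenerateInputError("zero pooled SD in table")
    j = 1.0 - 3.0 / (4.0 * m - 1.0)
    d = (obs["mean_treat"].to_numpy(float)
         - obs["mean_ctrl"].to_numpy(float)) / np.sqrt(sp2)
    g = j * d
    v = (nt + nc) / (nt * nc) + (1.0 - (m - 2.0) / (m * j**2)) * g**2
    out = obs.copy()
    out["g"] = g
    out["v"] = v
    out["m"] = m.astype(int)
    out["j"] = j
    return out
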