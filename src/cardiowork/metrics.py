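"""Agreement metrics between estimated and measured pressures and work
indices: total relative error, linear regression, Bland-Altman."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "total_relative_error",
    "regression_agreement",
    "bland_altman",
]


@dataclass
class AgreementReport:
    """Regression and Bland-Altman summary for one paired index."""

    slope: float
    intercept: float
    r2: float
    bias: float
    loa_low: float
    loa_high: float
    relative_bias_percent: float | None = None


def total_relative_error(p_lv_exp: np.ndarray, p_lv_model: np.ndarray,
                         pao_sys_exp: float, pao_sys_model: float,
                         pao_dias_exp: float, pao_dias_model: float) -> float:
    """Total relative error e% between estimated and measured pressures.

    e% = 50 |P_exp - P_model|_1 / |P_exp|_1
       + 50 (|dPao_sys|/Pao_sys_exp + |dPao_dias|/Pao_dias_exp)

    with the vectorial 1-norm over the sampled LV cycle.  Scale-invariant:
    rescaling all pressures by one positive constant leaves e% unchanged.
    """
    p_lv_exp = np.asarray(p_lv_exp, dtype=float)
    p_lv_model = np.asarray(p_lv_model, dtype=float)
    if p_lv_exp.shape != p_lv_model.shape:
        raise ValueError("LV traces must share one grid")
    norm = np.abs(p_lv_exp).sum()
    if norm == 0:
        raise ValueError("experimental LV trace has zero 1-norm")
    if pao_sys_exp <= 0 or pao_dias_exp <= 0:
        raise ValueError("aortic reference pressures must be > 0")
    e_lv = np.abs(p_lv_exp - p_lv_model).sum() / norm
    e_ao = (abs(pao_sys_exp - pao_sys_model) / abs(pao_sys_exp)
            + abs(pao_dias_exp - pao_dias_model) / abs(pao_dias_exp))
    return 50.0 * e_lv + 50.0 * e_ao


def regression_agreement(x: np.ndarray,
                         y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def bland_altman(exp_values, model_values,
                 relative_to_max: bool = True
                 ) -> tuple[float, tuple[float, float], float | None]:
    """Bland-Altman agreement of paired indices.

    Differences are model - experimental; bias is their mean and the 95%
    limits of agreement are bias +/- 1.96 SD.  The relative bias (percent)
    is the bias over the maximum experimental value across the cohort.
    """
    e = np.asarray(exp_values, dtype=float)
    m = np.asarray(model_values, dtype=float)
    if e.shape != m.shape:
        raise ValueError("unpaired value lists")
    if not (np.all(np.isfinite(e)) and np.all(np.isfinite(m))):
        raise ValueError("non-finite values")
    d = m - e
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    rel = None
    if relative_to_max and np.abs(e).max() > 0:
        rel = 100.0 * bias / float(np.abs(e).max())
    return bias, loa, rel
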