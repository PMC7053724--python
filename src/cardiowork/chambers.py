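"""Pressure-volume laws of the cardiac cavities.

Ventricles follow a time-varying elastance blending the linear end-systolic
pressure-volume relationship (ESPVR) with the exponential end-diastolic one
(EDPVR), driven by a normalised "double-Hill" activation function.  Atria
use a linear elastance modulated by a Gaussian driver that times the atrial
kick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "VentricleParams",
    "AtriumParams",
    "driver_double_hill",
    "driver_gain",
    "ventricle_pressure",
    "atrial_elastance",
    "atrial_pressure",
]

# cap on the EDPVR exponent; keeps exploratory (out-of-range) parameter
# draws from overflowing while leaving the physiologic regime untouched
_EXP_CAP = 40.0


@dataclass
class VentricleParams:
    """Ventricular elastance parameters.

    E_es   ESPVR slope (mmHg/mL); the maximal elastance once the driver is
           normalised to peak 1.
    V_d    ESPVR volume intercept (mL).
    P_0    EDPVR pressure gradient (mmHg).
    lam    EDPVR curvature (1/mL).
    V_0    EDPVR volume intercept (mL).
    alpha1, alpha2, n1, n2
           double-Hill shape parameters: contraction/relaxation timing
           fractions of the heart period and Hill steepness exponents.
    k      driver scale; ``None`` means "derive so that max e(t) = 1".
    """

    E_es: float = 3.0
    V_d: float = 10.0
    P_0: float = 0.9
    lam: float = 0.027
    V_0: float = 15.0
    alpha1: float = 0.303
    alpha2: float = 0.508
    n1: float = 1.32
    n2: float = 21.9
    k: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.E_es <= 0:
            raise ValueError("E_es must be > 0")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("Hill exponents n1, n2 must be >= 1")
        if not (0 < self.alpha1 < 1.5 and 0 < self.alpha2 < 1.5):
            raise ValueError("alpha1, alpha2 must lie in (0, 1.5)")


@dataclass
class AtriumParams:
    """Atrial elastance parameters.

    E_max/E_min  bounds of the atrial elastance (mmHg/mL); the literal peak
                 of the driver law is E_max + E_min (``peak_convention``
                 in :func:`atrial_elastance` switches to a peak of E_max).
    V_d          volume intercept (mL).
    B            Gaussian rate constant (1/s^2), sets the kick width.
    C            Gaussian centre (s) relative to atrial activation.
    """

    E_max: float = 0.25
    E_min: float = 0.10
    V_d: float = 4.0
    B: float = 200.0
    C: float = 0.15

    def __post_init__(self) -> None:
        if not (self.E_max >= self.E_min > 0):
            raise ValueError("need E_max >= E_min > 0")
        if self.B <= 0:
            raise ValueError("B must be > 0")
        if self.C < 0:
            raise ValueError("C must be >= 0")


def _double_hill_raw(t, T, alpha1, alpha2, n1, n2):
    x1 = (t / (alpha1 * T)) ** n1
    x2 = (t / (alpha2 * T)) ** n2
    return (x1 / (1.0 + x1)) * (1.0 / (1.0 + x2))


def driver_gain(params: VentricleParams, T: float) -> float:
    """Scale factor k such that max over t of the double-Hill driver is 1.

    With this normalisation ``E_es`` is the true maximal elastance.  The
    maximum is located by a dense grid scan refined with bounded scalar
    minimisation (the driver is smooth and unimodal in practice).
    """
    if params.k is not None:
        return params.k
    tt = np.linspace(1e-9, T, 2048)
    vals = _double_hill_raw(tt, T, params.alpha1, params.alpha2,
                            params.n1, params.n2)
    i = int(np.argmax(vals))
    lo = tt[max(i - 1, 0)]
    hi = tt[min(i + 1, len(tt) - 1)]
    res = minimize_scalar(
        lambda t: -_double_hill_raw(t, T, params.alpha1, params.alpha2,
                                    params.n1, params.n2),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    peak = max(-res.fun, vals[i])
    return 1.0 / peak


def driver_double_hill(t, params: VentricleParams, T: float,
                       k: float | None = None):
    """Normalised ventricular driver e(t) in [0, 1].

    ``t`` is time since ventricular activation (scalar or array).  The
    driver is the product of a Hill-type contraction factor and a Hill-type
    relaxation factor, scaled by ``k`` (derived so that the maximum is 1
    unless given explicitly).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("driver time must be >= 0")
    if k is None:
        k = driver_gain(params, T)
    e = k * _double_hill_raw(np.maximum(t, 1e-300), T,
                             params.alpha1, params.alpha2,
                             params.n1, params.n2)
    return e if e.ndim else float(e)


def ventricle_pressure(V, t, params: VentricleParams, T: float,
                       e=None):
    """Instantaneous ventricular pressure (mmHg).

    P = e * E_es (V - V_d) + (1 - e) * P_0 (exp(lam (V - V_0)) - 1),
    a driver-weighted blend of the ESPVR and EDPVR.  ``e`` may be supplied
    directly (e.g. by the integrator); otherwise it is evaluated from the
    double-Hill driver at ``t``.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("ventricular volume must be > 0")
    if e is None:
        e = driver_double_hill(t, params, T)
    p_es = params.E_es * (V - params.V_d)
    p_ed = params.P_0 * (np.exp(np.minimum(params.lam * (V - params.V_0),
                                           _EXP_CAP)) - 1.0)
    p = e * p_es + (1.0 - e) * p_ed
    return p if p.ndim else float(p)


def atrial_elastance(t, params: AtriumParams,
                     peak_convention: str = "sum"):
    """Time-varying atrial elastance E_la(t) (mmHg/mL).

    E(t) = E_max (exp(-B (t - C)^2) + E_min/E_max) with the literal law
    peaking at E_max + E_min (``peak_convention="sum"``, the default);
    ``peak_convention="max"`` rescales the Gaussian so the peak is E_max.
    """
    t = np.asarray(t, dtype=float)
    g = np.exp(-params.B * (t - params.C) ** 2)
    if peak_convention == "sum":
        e = params.E_max * g + params.E_min
    elif peak_convention == "max":
        e = (params.E_max - params.E_min) * g + params.E_min
    else:
        raise ValueError("peak_convention must be 'sum' or 'max'")
    return e if e.ndim else float(e)


def atrial_pressure(V, t, params: AtriumParams,
                    peak_convention: str = "sum"):
    """Atrial pressure P = E_la(t) (V - V_d) (mmHg).

    ``t`` is time since atrial activation.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("atrial volume must be > 0")
    p = atrial_elastance(t, params, peak_convention) * (V - params.V_d)
    return p if np.ndim(p) else float(p)
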