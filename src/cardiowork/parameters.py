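"""The full model parameter set and its identified-parameter views.

``ParameterSet`` gathers the electrical network, the four cardiac cavities,
the four valves and the circulation.  Two named views matter for
patient-specific estimation:

* ``X_LV``  — the ventricular parameters identified in step 1
  (E_es, lambda, P_0, alpha1, alpha2, n1, n2 of the left ventricle);
* ``X_art`` — the circulatory parameters identified in both steps
  (aortic/arterial/venous/caval elastances and unstressed volumes plus the
  three systemic resistances).

Parameters are addressed by dotted paths such as ``"lv.E_es"`` or
``"circ.R_sys"`` so that sensitivity analysis and identification can treat
the set as a flat vector.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields

import numpy as np

from .chambers import AtriumParams, VentricleParams, driver_gain
from .circulation import CirculationParams
from .electrical import Network, standard_network
from .valves import ValveParams

__all__ = [
    "ParameterSet",
    "X_LV_NAMES",
    "X_ART_NAMES",
    "nominal_parameters",
    "get_param",
    "set_param",
    "pack_kernel_params",
    "initial_state",
    "STATE_NAMES",
    "N_STATE",
]

X_LV_NAMES = (
    "lv.E_es", "lv.lam", "lv.P_0",
    "lv.alpha1", "lv.alpha2", "lv.n1", "lv.n2",
)
X_ART_NAMES = (
    "circ.E_ao", "circ.E_vc", "circ.E_sa", "circ.E_sv",
    "circ.Vd_ao", "circ.Vd_vc", "circ.Vd_sa", "circ.Vd_sv",
    "circ.R_ao", "circ.R_sys", "circ.R_vc",
)

#: state-vector layout used by the integrator
STATE_NAMES = (
    "V_lv", "V_la", "V_rv", "V_ra",
    "V_ao", "V_sa", "V_sv", "V_vc", "V_pa", "V_pv",
    "Q_mitral", "Q_aortic", "Q_tricuspid", "Q_pulmonary",
    "xi_mitral", "xi_aortic", "xi_tricuspid", "xi_pulmonary",
)
N_STATE = len(STATE_NAMES)


def _default_valves() -> dict[str, ValveParams]:
    return {
        "mitral": ValveParams(A_max=4.0, l_eff=1.8, K_vo=20.0, K_vc=25.0),
        "aortic": ValveParams(A_max=2.5, l_eff=1.5, K_vo=12.0, K_vc=12.0),
        "tricuspid": ValveParams(A_max=5.0, l_eff=1.8, K_vo=20.0, K_vc=25.0),
        "pulmonary": ValveParams(A_max=3.0, l_eff=1.5, K_vo=12.0, K_vc=12.0),
    }


@dataclass
class ParameterSet:
    """All model constants, with the X_LV / X_art identified views."""

    T: float = 1.0
    lv: VentricleParams = field(default_factory=VentricleParams)
    rv: VentricleParams = field(default_factory=lambda: VentricleParams(
        E_es=0.55, V_d=5.0, P_0=0.6, lam=0.022, V_0=10.0))
    la: AtriumParams = field(default_factory=AtriumParams)
    ra: AtriumParams = field(default_factory=lambda: AtriumParams(
        E_max=0.20, E_min=0.07))
    valves: dict[str, ValveParams] = field(default_factory=_default_valves)
    circ: CirculationParams = field(default_factory=CirculationParams)
    electrical: Network | None = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("heart period T must be > 0")
        missing = {"mitral", "aortic", "tricuspid", "pulmonary"} - \
            set(self.valves)
        if missing:
            raise ValueError(f"missing valves: {sorted(missing)}")

    def network(self) -> Network:
        """The conduction network (standard seven-automaton net by default,
        with the pacemaker period equal to ``T``)."""
        if self.electrical is not None:
            return self.electrical
        return standard_network(self.T)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- flat-vector views -------------------------------------------------
    def x_lv(self) -> np.ndarray:
        return np.array([get_param(self, n) for n in X_LV_NAMES])

    def x_art(self) -> np.ndarray:
        return np.array([get_param(self, n) for n in X_ART_NAMES])

    def with_values(self, names, values) -> "ParameterSet":
        """A copy with the dotted-path parameters set to ``values``."""
        ps = self.copy()
        for name, value in zip(names, values, strict=True):
            set_param(ps, name, float(value))
        return ps


def nominal_parameters(T: float = 1.0) -> ParameterSet:
    """The nominal (healthy-subject) parameter set at heart period ``T``."""
    return ParameterSet(T=T)


def get_param(ps: ParameterSet, path: str) -> float:
    """Fetch a parameter by dotted path, e.g. ``"lv.E_es"`` or
    ``"valves.aortic.A_max"``."""
    obj = ps
    for part in path.split("."):
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    return obj


def set_param(ps: ParameterSet, path: str, value: float) -> None:
    """Assign a parameter by dotted path (in place)."""
    obj = ps
    parts = path.split(".")
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    if isinstance(obj, dict):
        obj[parts[-1]] = value
    else:
        if not hasattr(obj, parts[-1]):
            raise AttributeError(f"unknown parameter {path!r}")
        setattr(obj, parts[-1], value)


# ---------------------------------------------------------------------------
# packing for the compiled integrator
# ---------------------------------------------------------------------------
# flat float64 layout (documented indices; the kernel hard-codes them):
#   0        T
#   1..10    LV:  E_es V_d P_0 lam V_0 alpha1 alpha2 n1 n2 k
#   11..20   RV:  same
#   21..25   LA:  E_max E_min V_d B C
#   26..30   RA:  same
#   31..54   valves (mitral, aortic, tricuspid, pulmonary), 6 each:
#            A_max A_min b_coef l_coef K_vo K_vc
#   55..60   E_ao E_sa E_sv E_vc E_pa E_pv
#   61..66   Vd_ao Vd_sa Vd_sv Vd_vc Vd_pa Vd_pv
#   67..72   R_ao R_sys R_vc R_ra R_pul R_pv

N_KERNEL_PARAMS = 73
VALVE_ORDER = ("mitral", "aortic", "tricuspid", "pulmonary")


def pack_kernel_params(ps: ParameterSet) -> np.ndarray:
    p = np.empty(N_KERNEL_PARAMS)
    p[0] = ps.T
    for base, v in ((1, ps.lv), (11, ps.rv)):
        p[base:base + 9] = (v.E_es, v.V_d, v.P_0, v.lam, v.V_0,
                            v.alpha1, v.alpha2, v.n1, v.n2)
        p[base + 9] = driver_gain(v, ps.T)
    for base, a in ((21, ps.la), (26, ps.ra)):
        p[base:base + 5] = (a.E_max, a.E_min, a.V_d, a.B, a.C)
    for i, name in enumerate(VALVE_ORDER):
        vp = ps.valves[name]
        base = 31 + 6 * i
        p[base:base + 6] = (vp.A_max, vp.A_min, vp.b_coef, vp.l_coef,
                            vp.K_vo, vp.K_vc)
    c = ps.circ
    p[55:61] = (c.E_ao, c.E_sa, c.E_sv, c.E_vc, c.E_pa, c.E_pv)
    p[61:67] = (c.Vd_ao, c.Vd_sa, c.Vd_sv, c.Vd_vc, c.Vd_pa, c.Vd_pv)
    p[67:73] = (c.R_ao, c.R_sys, c.R_vc, c.R_ra, c.R_pul, c.R_pv)
    return p


def initial_state(ps: ParameterSet) -> np.ndarray:
    """Physiologic starting state: volumes near their unstressed values with
    systemic offsets, all valves closed and flowless.

    The systemic-vein volume absorbs the remainder of the total blood
    volume so that the closed-loop total matches ``circ.total_volume``.
    """
    c = ps.circ
    y = np.zeros(N_STATE)
    y[0] = 130.0                 # V_lv
    y[1] = ps.la.V_d + 50.0      # V_la
    y[2] = 120.0                 # V_rv
    y[3] = ps.ra.V_d + 50.0      # V_ra
    y[4] = c.Vd_ao + 70.0
    y[5] = c.Vd_sa + 90.0
    y[7] = c.Vd_vc + 150.0
    y[8] = c.Vd_pa + 35.0
    y[9] = c.Vd_pv + 200.0
    rest = c.total_volume - (y[:10].sum())
    if rest <= c.Vd_sv:
        raise ValueError("total blood volume too small for the configured "
                         "unstressed volumes")
    y[6] = rest
    return y
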