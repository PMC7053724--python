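"""Pressure-strain myocardial work indices.

Segmental instantaneous power is the product of the strain rate (from
differentiating the segmental longitudinal strain curve) and the
instantaneous LV pressure; integrating it from mitral valve closure (MVC)
to mitral valve opening (MVO) gives the cumulative segmental work.  The
work trace is split into systole (S: MVC to aortic valve closure, AVC) and
isovolumic relaxation (IVR: AVC to MVO); within each phase, the summed
increments of ascending runs give the positive work Wp and the summed
magnitudes of descending runs the negative work Wn.  Shortening against
pressure during S and lengthening during IVR are constructive; stretching
during S and shortening during IVR are wasted:

    GCW = mean_k(Wp_S + Wn_IVR),   GWW = mean_k(Wn_S + Wp_IVR),
    GWE = GCW / (GCW + GWW).

Work is reported in mmHg.%, the clinical convention for pressure-strain
work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StrainSet",
    "WorkIndices",
    "instantaneous_power",
    "segmental_work",
    "decompose_work",
    "global_indices",
    "compute_work_indices",
]

#: dead-band on successive work increments; ties break toward run
#: continuation
RUN_TOL = 1e-12


@dataclass
class StrainSet:
    """K segmental strain traces (%) on a shared uniform time grid, with
    the valve event times delimiting the analysed cycle."""

    t: np.ndarray
    strain: np.ndarray          # (n, K)
    mvc: float
    avo: float
    avc: float
    mvo: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.strain = np.atleast_2d(np.asarray(self.strain, dtype=float))
        if self.strain.shape[0] != self.t.size:
            self.strain = self.strain.T
        if self.strain.shape[0] != self.t.size:
            raise ValueError("strain traces must share the time grid")
        if not (self.mvc < self.avc < self.mvo):
            raise ValueError("need MVC < AVC < MVO within the cycle")

    @property
    def n_segments(self) -> int:
        return self.strain.shape[1]


@dataclass
class WorkIndices:
    """Per-segment phase work components and the global indices."""

    wp_s: np.ndarray
    wn_s: np.ndarray
    wp_ivr: np.ndarray
    wn_ivr: np.ndarray
    gcw: float = field(init=False)
    gww: float = field(init=False)
    gwe: float = field(init=False)

    def __post_init__(self) -> None:
        for a in (self.wp_s, self.wn_s, self.wp_ivr, self.wn_ivr):
            if np.any(np.asarray(a) < 0):
                raise ValueError("phase work components must be >= 0")
        self.gcw = float(np.mean(self.wp_s + self.wn_ivr))
        self.gww = float(np.mean(self.wn_s + self.wp_ivr))
        tot = self.gcw + self.gww
        self.gwe = self.gcw / tot if tot > 0 else math.nan


def instantaneous_power(t: np.ndarray, strain: np.ndarray,
                        p_lv: np.ndarray,
                        shortening_positive: bool = True) -> np.ndarray:
    """Segmental power (mmHg.%/s): strain rate times LV pressure.

    ``strain`` may be (n,) or (n, K); the strain rate uses central
    differences on the uniform grid (no pre-smoothing).

    With ``shortening_positive`` (the default) the sign convention is
    power = -(d eps/dt) P, so that fibre shortening against pressure
    accumulates an ascending work curve during systole — the convention
    the constructive/wasted decomposition is defined on.  Set it False for
    the raw product (d eps/dt) P.
    """
    t = np.asarray(t, dtype=float)
    strain = np.asarray(strain, dtype=float)
    p_lv = np.asarray(p_lv, dtype=float)
    if strain.shape[0] != t.size or p_lv.size != t.size:
        raise ValueError("strain, pressure and time grids are misaligned")
    rate = np.gradient(strain, t, axis=0)
    sign = -1.0 if shortening_positive else 1.0
    return sign * rate * (p_lv[:, None] if strain.ndim == 2 else p_lv)


def segmental_work(t: np.ndarray, power: np.ndarray, mvc: float,
                   mvo: float) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative work w(t) = integral of power from MVC, over [MVC, MVO].

    Returns (t_window, w) with w starting at 0; trapezoidal integration.
    """
    t = np.asarray(t, dtype=float)
    power = np.asarray(power, dtype=float)
    if not (t[0] <= mvc < mvo <= t[-1]):
        raise ValueError("MVC/MVO outside the sampled grid")
    mask = (t >= mvc) & (t <= mvo)
    tw = t[mask]
    pw = power[mask]
    if pw.ndim == 1:
        w = np.concatenate([[0.0], np.cumsum(
            0.5 * (pw[1:] + pw[:-1]) * np.diff(tw))])
    else:
        w = np.vstack([np.zeros(pw.shape[1]), np.cumsum(
            0.5 * (pw[1:] + pw[:-1]) * np.diff(tw)[:, None], axis=0)])
    return tw, w


def _run_totals(w: np.ndarray) -> tuple[float, float]:
    """(ascending, descending) totals of a trace via maximal monotone runs.

    Increments within the dead band continue the current run, so the
    ascending total is the sum of positive increments and the descending
    total the summed magnitude of negative ones (the run partition
    telescopes to exactly this).
    """
    d = np.diff(np.asarray(w, dtype=float))
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite samples in work trace")
    up = d[d > RUN_TOL].sum()
    down = -d[d < -RUN_TOL].sum()
    return float(up), float(down)


def decompose_work(t: np.ndarray, w: np.ndarray, mvc: float, avc: float,
                   mvo: float) -> tuple[float, float, float, float]:
    """Split one segment's cumulative work into (Wp_S, Wn_S, Wp_IVR, Wn_IVR).

    S spans MVC to AVC, IVR spans AVC to MVO; all four components are
    non-negative magnitudes.
    """
    if not (mvc < avc < mvo):
        raise ValueError("need MVC < AVC < MVO")
    t = np.asarray(t, dtype=float)
    w = np.asarray(w, dtype=float)
    s_mask = (t >= mvc) & (t <= avc)
    r_mask = (t >= avc) & (t <= mvo)
    wp_s, wn_s = _run_totals(w[s_mask])
    wp_ivr, wn_ivr = _run_totals(w[r_mask])
    return wp_s, wn_s, wp_ivr, wn_ivr


def global_indices(wp_s, wn_s, wp_ivr, wn_ivr) -> WorkIndices:
    """Aggregate per-segment components into GCW, GWW and GWE."""
    return WorkIndices(wp_s=np.atleast_1d(np.asarray(wp_s, dtype=float)),
                       wn_s=np.atleast_1d(np.asarray(wn_s, dtype=float)),
                       wp_ivr=np.atleast_1d(np.asarray(wp_ivr, dtype=float)),
                       wn_ivr=np.atleast_1d(np.asarray(wn_ivr, dtype=float)))


def compute_work_indices(strain_set: StrainSet,
                         p_lv: np.ndarray) -> WorkIndices:
    """Full pipeline: power, cumulative work, phase decomposition, global
    indices, for all segments of a :class:`StrainSet` against an LV
    pressure trace sampled on the same grid."""
    power = instantaneous_power(strain_set.t, strain_set.strain, p_lv)
    tw, w = segmental_work(strain_set.t, power, strain_set.mvc,
                           strain_set.mvo)
    comps = np.array([
        decompose_work(tw, w[:, k], strain_set.mvc, strain_set.avc,
                       strain_set.mvo)
        for k in range(strain_set.n_segments)
    ])
    return global_indices(comps[:, 0], comps[:, 1], comps[:, 2], comps[:, 3])
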