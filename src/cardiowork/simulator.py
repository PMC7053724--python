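"""Closed-loop cardiovascular simulation.

Assembles the conduction network, cardiac cavities, valves and circulation
into one ODE system, integrates it beat by beat to a periodic steady state
and returns a uniformly sampled :class:`SimulationResult` with per-beat
valve events (MVC/AVO/AVC/MVO), QRS markers and the derived scalars used
downstream (systolic/diastolic aortic pressure, peak LV pressure and the
transvalvular gradient dP = max P_LV - Pao_sys).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .chambers import atrial_pressure, driver_double_hill, driver_gain, \
    ventricle_pressure
from .circulation import VESSELS, vessel_pressure
from .electrical import run_conduction
from .parameters import (N_STATE, STATE_NAMES, VALVE_ORDER, ParameterSet,
                         initial_state, pack_kernel_params)
from .valves import ValveParams, ValveState, valve_derivatives

__all__ = [
    "SolverConfig",
    "SimulationResult",
    "SimulationError",
    "derivatives",
    "simulate",
    "detect_valve_events",
    "pressure_gradient",
]


class SimulationError(RuntimeError):
    """Integration failure (non-finite state or impossible schedule)."""


@dataclass
class SolverConfig:
    """Fixed-step integrator settings.

    dt            internal RK4 step (s); 0.25 ms resolves the valve rate law.
    sample_dt     output grid step (s), 1 ms by default.
    xi_threshold  opening fraction defining valve open/closed events.
    steady_rtol   relative beat-to-beat tolerance (max LV pressure and
                  stroke volume) declaring periodic steady state.
    """

    dt: float = 2.5e-4
    sample_dt: float = 1.0e-3
    xi_threshold: float = 0.05
    steady_rtol: float = 5.0e-3

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.sample_dt <= 0:
            raise ValueError("time steps must be > 0")
        if self.sample_dt < self.dt:
            raise ValueError("sample_dt must be >= dt")


@dataclass
class BeatEvents:
    """Valve event times (s) of one beat, ordered MVC < AVO < AVC < MVO."""

    start: float
    end: float
    mvc: float | None = None
    avo: float | None = None
    avc: float | None = None
    mvo: float | None = None

    @property
    def complete(self) -> bool:
        return None not in (self.mvc, self.avo, self.avc, self.mvo)


@dataclass
class SimulationResult:
    """Uniformly sampled simulation output plus event markers and scalars."""

    t: np.ndarray
    states: np.ndarray              # (n, 18), parameters.STATE_NAMES order
    pressures: dict[str, np.ndarray]
    qrs: list[float]
    beats: list[BeatEvents]
    converged: bool
    params: ParameterSet
    solver: SolverConfig
    analysis_slice: slice = field(default_factory=lambda: slice(0, 0))

    # -- convenience views -------------------------------------------------
    def volume(self, chamber: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(f"V_{chamber}")]

    def flow(self, valve: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(f"Q_{valve}")]

    def xi(self, valve: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(f"xi_{valve}")]

    @property
    def analysis_beat(self) -> BeatEvents:
        return self.beats[-1]

    # -- derived scalars (analysis = last complete beat) -------------------
    @property
    def pao_sys(self) -> float:
        return float(self.pressures["ao"][self.analysis_slice].max())

    @property
    def pao_dias(self) -> float:
        return float(self.pressures["ao"][self.analysis_slice].min())

    @property
    def p_lv_max(self) -> float:
        return float(self.pressures["lv"][self.analysis_slice].max())

    @property
    def delta_p(self) -> float:
        return self.p_lv_max - self.pao_sys

    def beat_pressure(self, chamber: str = "lv") -> tuple[np.ndarray,
                                                          np.ndarray]:
        """(t_rel, P) of the analysis beat, time measured from its QRS."""
        sl = self.analysis_slice
        t = self.t[sl]
        return t - t[0], self.pressures[chamber][sl]

    def total_volume(self) -> np.ndarray:
        return self.states[:, :10].sum(axis=1)

    def to_frame(self):
        """All sampled signals as a pandas DataFrame (time_s index)."""
        import pandas as pd

        data = {name: self.states[:, i] for i, name in enumerate(STATE_NAMES)}
        for name, p in self.pressures.items():
            data[f"P_{name}"] = p
        return pd.DataFrame(data, index=pd.Index(self.t, name="time_s"))


def derivatives(y: np.ndarray, t: float, ps: ParameterSet,
                activation_context: tuple[float, float, float, float]
                ) -> np.ndarray:
    """Pure-Python reference right-hand side.

    ``activation_context`` carries the four driver clocks (time since the
    latest LV, RV, LA, RA activation).  This mirrors the compiled kernel and
    exists for transparency and cross-checking; :func:`simulate` uses the
    compiled path.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (N_STATE,):
        raise ValueError(f"state must have shape ({N_STATE},)")
    if not np.all(np.isfinite(y)):
        raise SimulationError(f"non-finite state at t={t}: {y}")
    tau_lv, tau_rv, tau_la, tau_ra = activation_context
    dy = np.zeros(N_STATE)

    e_lv = driver_double_hill(max(tau_lv, 0.0), ps.lv, ps.T)
    e_rv = driver_double_hill(max(tau_rv, 0.0), ps.rv, ps.T)
    P = {
        "lv": ventricle_pressure(y[0], tau_lv, ps.lv, ps.T, e=e_lv),
        "la": atrial_pressure(y[1], tau_la, ps.la),
        "rv": ventricle_pressure(y[2], tau_rv, ps.rv, ps.T, e=e_rv),
        "ra": atrial_pressure(y[3], tau_ra, ps.ra),
    }
    c = ps.circ
    for i, name in enumerate(VESSELS):
        P[name] = vessel_pressure(y[4 + i], getattr(c, f"E_{name}"),
                                  getattr(c, f"Vd_{name}"))

    heads = {
        "mitral": P["la"] - P["lv"],
        "aortic": P["lv"] - P["ao"],
        "tricuspid": P["ra"] - P["rv"],
        "pulmonary": P["rv"] - P["pa"],
    }
    for i, name in enumerate(VALVE_ORDER):
        state = ValveState(Q=y[10 + i], xi=float(np.clip(y[14 + i], 0, 1)))
        dQ, dxi = valve_derivatives(heads[name], state, ps.valves[name])
        dy[10 + i] = dQ
        dy[14 + i] = dxi

    q_ao_sa = (P["ao"] - P["sa"]) / c.R_ao
    q_sa_sv = (P["sa"] - P["sv"]) / c.R_sys
    q_sv_vc = (P["sv"] - P["vc"]) / c.R_vc
    q_vc_ra = (P["vc"] - P["ra"]) / c.R_ra
    q_pa_pv = (P["pa"] - P["pv"]) / c.R_pul
    q_pv_la = (P["pv"] - P["la"]) / c.R_pv

    dy[0] = y[10] - y[11]
    dy[1] = q_pv_la - y[10]
    dy[2] = y[12] - y[13]
    dy[3] = q_vc_ra - y[12]
    dy[4] = y[11] - q_ao_sa
    dy[5] = q_ao_sa - q_sa_sv
    dy[6] = q_sa_sv - q_sv_vc
    dy[7] = q_sv_vc - q_vc_ra
    dy[8] = y[13] - q_pa_pv
    dy[9] = q_pa_pv - q_pv_la
    return dy


def _taus(t: np.ndarray, act: np.ndarray, T: float) -> np.ndarray:
    """Time since the latest activation <= t (virtual activation at
    act[0] - T before the first one)."""
    if act.size == 0:
        return t + T
    idx = np.searchsorted(act, t, side="right") - 1
    last = np.where(idx >= 0, act[np.maximum(idx, 0)], act[0] - T)
    return t - last


def simulate(ps: ParameterSet, n_beats: int = 15,
             solver: SolverConfig | None = None,
             y0: np.ndarray | None = None) -> SimulationResult:
    """Integrate the closed loop over ``n_beats`` cardiac cycles.

    The conduction network is run first (event-driven); its activation times
    drive the mechanical model.  Beats are delimited by LV activations (QRS
    markers).  The final beat is the analysis beat; ``converged`` reports
    whether the last two beats agree in peak LV pressure and stroke volume
    to within ``solver.steady_rtol``.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    solver = solver or SolverConfig()
    schedule = run_conduction(ps.network(), (n_beats + 2) * ps.T)
    act = {}
    for name in ("LV", "RV", "LA", "RA"):
        act[name] = np.asarray(schedule.activations.get(name, []), dtype=float)
    if act["LV"].size < n_beats + 1:
        raise SimulationError("conduction network produced too few "
                              "ventricular activations")
    t_end = float(act["LV"][n_beats])
    y0 = initial_state(ps) if y0 is None else np.asarray(y0, dtype=float)
    p = pack_kernel_params(ps)
    sample_every = max(1, int(round(solver.sample_dt / solver.dt)))
    ts, ys, ok = _kernel.integrate(
        y0, 0.0, t_end, solver.dt, sample_every, p,
        act["LV"], act["RV"], act["LA"], act["RA"])
    if not ok:
        raise SimulationError(
            "non-finite state during integration; last finite sample at "
            f"t={ts[-1]:.4f}s, state={ys[-1]}")

    pressures = _pressures(ts, ys, ps, act)
    qrs = [float(a) for a in act["LV"] if a <= ts[-1]]
    beats = detect_valve_events_arrays(ts, ys, qrs, solver.xi_threshold)

    # analysis window: the last complete beat
    i0 = np.searchsorted(ts, qrs[-2]) if len(qrs) >= 2 else 0
    i1 = np.searchsorted(ts, qrs[-1]) if len(qrs) >= 2 else len(ts)
    analysis = slice(int(i0), int(i1) + 1)

    converged = _steady(ts, ys, pressures, qrs, solver.steady_rtol)
    if not converged:
        warnings.warn("simulation did not reach periodic steady state; "
                      "increase n_beats", RuntimeWarning, stacklevel=2)
    return SimulationResult(t=ts, states=ys, pressures=pressures, qrs=qrs,
                            beats=beats, converged=converged, params=ps,
                            solver=solver, analysis_slice=analysis)


def _pressures(ts, ys, ps: ParameterSet, act) -> dict[str, np.ndarray]:
    tau_lv = _taus(ts, act["LV"], ps.T)
    tau_rv = _taus(ts, act["RV"], ps.T)
    tau_la = _taus(ts, act["LA"], ps.T)
    tau_ra = _taus(ts, act["RA"], ps.T)
    k_lv = driver_gain(ps.lv, ps.T)
    k_rv = driver_gain(ps.rv, ps.T)
    e_lv = driver_double_hill(tau_lv, ps.lv, ps.T, k=k_lv)
    e_rv = driver_double_hill(tau_rv, ps.rv, ps.T, k=k_rv)
    out = {
        "lv": ventricle_pressure(ys[:, 0], None, ps.lv, ps.T, e=e_lv),
        "la": atrial_pressure(ys[:, 1], tau_la, ps.la),
        "rv": ventricle_pressure(ys[:, 2], None, ps.rv, ps.T, e=e_rv),
        "ra": atrial_pressure(ys[:, 3], tau_ra, ps.ra),
    }
    c = ps.circ
    for i, name in enumerate(VESSELS):
        out[name] = vessel_pressure(ys[:, 4 + i], getattr(c, f"E_{name}"),
                                    getattr(c, f"Vd_{name}"))
    return out


def _steady(ts, ys, pressures, qrs, rtol) -> bool:
    if len(qrs) < 3:
        return False
    p_lv = pressures["lv"]
    v_lv = ys[:, 0]
    stats = []
    for a, b in zip(qrs[-3:-1], qrs[-2:]):
        sl = slice(int(np.searchsorted(ts, a)), int(np.searchsorted(ts, b)))
        if sl.stop <= sl.start:
            return False
        sv = v_lv[sl].max() - v_lv[sl].min()
        stats.append((p_lv[sl].max(), sv))
    (p1, sv1), (p2, sv2) = stats
    return bool(abs(p2 - p1) <= rtol * max(abs(p1), 1.0)
                and abs(sv2 - sv1) <= rtol * max(abs(sv1), 1.0))


def _cross_times(ts, trace, threshold, rising: bool) -> np.ndarray:
    """Linear-interpolated crossing times of ``trace`` through threshold."""
    above = trace >= threshold
    if rising:
        idx = np.flatnonzero(~above[:-1] & above[1:])
    else:
        idx = np.flatnonzero(above[:-1] & ~above[1:])
    if idx.size == 0:
        return np.empty(0)
    f = (threshold - trace[idx]) / (trace[idx + 1] - trace[idx])
    return ts[idx] + f * (ts[idx + 1] - ts[idx])


def detect_valve_events_arrays(ts, ys, qrs, threshold=0.05) -> list[BeatEvents]:
    """Per-beat MVC/AVO/AVC/MVO from the valve opening fractions.

    Opening is the upward crossing of xi through ``threshold``, closure the
    downward crossing.  Beats are the intervals between consecutive QRS
    markers; per-beat ordering MVC < AVO < AVC < MVO is resolved by
    searching each event after the previous one.
    """
    xi_mit = ys[:, 14]
    xi_aor = ys[:, 15]
    mvc_all = _cross_times(ts, xi_mit, threshold, rising=False)
    mvo_all = _cross_times(ts, xi_mit, threshold, rising=True)
    avo_all = _cross_times(ts, xi_aor, threshold, rising=True)
    avc_all = _cross_times(ts, xi_aor, threshold, rising=False)

    def first_in(cands, lo, hi):
        sel = cands[(cands >= lo) & (cands < hi)]
        return float(sel[0]) if sel.size else None

    beats = []
    for a, b in zip(qrs[:-1], qrs[1:]):
        ev = BeatEvents(start=float(a), end=float(b))
        ev.mvc = first_in(mvc_all, a, b)
        lo = ev.mvc if ev.mvc is not None else a
        ev.avo = first_in(avo_all, lo, b)
        lo = ev.avo if ev.avo is not None else lo
        ev.avc = first_in(avc_all, lo, b)
        lo = ev.avc if ev.avc is not None else lo
        ev.mvo = first_in(mvo_all, lo, b)
        beats.append(ev)
    return beats


def detect_valve_events(result: SimulationResult,
                        threshold: float | None = None) -> list[BeatEvents]:
    """Valve events of an existing simulation (see the array variant)."""
    thr = threshold if threshold is not None else result.solver.xi_threshold
    return detect_valve_events_arrays(result.t, result.states, result.qrs,
                                      thr)


def pressure_gradient(result: SimulationResult) -> float:
    """Transvalvular gradient dP = max(P_LV) - Pao_sys on the analysis
    beat (mmHg)."""
    return result.delta_p
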