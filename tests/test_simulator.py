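import numpy as np
import pytest

from cardiowork import _kernel
from cardiowork.electrical import run_conduction
from cardiowork.parameters import (N_STATE, initial_state,
                                   nominal_parameters, pack_kernel_params,
                                   set_param)
from cardiowork.simulator import (SolverConfig, derivatives,
                                  detect_valve_events,
                                  detect_valve_events_arrays,
                                  pressure_gradient, simulate)


class TestDerivatives:
    def test_python_reference_matches_compiled_kernel(self):
        """The pure-Python RHS and the compiled kernel implement the same
        laws (checked on random physiologic states)."""
        ps = nominal_parameters()
        p = pack_kernel_params(ps)
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = initial_state(ps)
            y[:10] *= rng.uniform(0.7, 1.3, 10)
            y[10:14] = rng.normal(0, 200, 4)
            y[14:18] = rng.uniform(0, 1, 4)
            taus = tuple(rng.uniform(0.0, 1.0, 4))
            dy_py = derivatives(y, 0.0, ps, taus)
            dy_k = np.empty(N_STATE)
            _kernel.rhs(y, *taus, p, dy_k)
            assert dy_py == pytest.approx(dy_k, rel=1e-10, abs=1e-10)

    def test_equilibrium_state_has_zero_derivatives(self):
        """With every chamber at one common pressure, drivers quiescent
        and valves at their fixed points, all derivatives vanish."""
        ps = nominal_parameters()
        P = 8.0
        tau_quiet = 10.0 * ps.T         # drivers fully relaxed
        y = np.zeros(N_STATE)
        # invert each pressure law for the common pressure P
        y[0] = ps.lv.V_0 + np.log(P / ps.lv.P_0 + 1.0) / ps.lv.lam
        y[2] = ps.rv.V_0 + np.log(P / ps.rv.P_0 + 1.0) / ps.rv.lam
        y[1] = ps.la.V_d + P / ps.la.E_min
        y[3] = ps.ra.V_d + P / ps.ra.E_min
        for i, name in enumerate(("ao", "sa", "sv", "vc", "pa", "pv")):
            E = getattr(ps.circ, f"E_{name}")
            vd = getattr(ps.circ, f"Vd_{name}")
            y[4 + i] = vd + P / E
        y[14:18] = 1.0                  # open valves, dP=0 -> no drive
        dy = derivatives(y, 0.0, ps, (tau_quiet,) * 4)
        assert np.allclose(dy, 0.0, atol=1e-6)

    def test_locality_of_volume_perturbation(self):
        """Perturbing one vessel volume only changes the flows touching
        that chamber."""
        ps = nominal_parameters()
        y = initial_state(ps)
        taus = (0.4, 0.4, 0.45, 0.45)
        base = derivatives(y, 0.0, ps, taus)
        y2 = y.copy()
        y2[5] += 10.0                   # systemic-artery volume
        pert = derivatives(y2, 0.0, ps, taus)
        changed = np.flatnonzero(~np.isclose(base, pert, rtol=1e-12,
                                             atol=1e-12))
        # only V_ao, V_sa, V_sv rates change (the two resistors at sa)
        assert set(changed) <= {4, 5, 6}

    def test_nan_state_raises_with_diagnostic(self):
        ps = nominal_parameters()
        y = initial_state(ps)
        y[0] = np.nan
        with pytest.raises(Exception, match="non-finite"):
            derivatives(y, 0.0, ps, (0.1,) * 4)


class TestSimulate:
    def test_periodic_steady_state_reached(self, healthy_sim):
        assert healthy_sim.converged
        # beat-to-beat peak LV pressure stable
        p_lv = healthy_sim.pressures["lv"]
        qrs = healthy_sim.qrs
        peaks = []
        for a, b in zip(qrs[-4:-1], qrs[-3:]):
            sl = slice(np.searchsorted(healthy_sim.t, a),
                       np.searchsorted(healthy_sim.t, b))
            peaks.append(p_lv[sl].max())
        assert np.ptp(peaks) < 0.5

    def test_volume_conservation(self, healthy_sim):
        total = healthy_sim.total_volume()
        drift = np.ptp(total) / total[0]
        assert drift < 1e-3

    def test_all_volumes_positive_and_xi_bounded(self, healthy_sim):
        assert healthy_sim.states[:, :10].min() > 0
        xi = healthy_sim.states[:, 14:18]
        assert xi.min() >= 0.0
        assert xi.max() <= 1.0

    def test_event_ordering_within_beats(self, healthy_sim):
        complete = [b for b in healthy_sim.beats if b.complete]
        assert len(complete) >= 10
        for b in complete:
            assert b.start <= b.mvc < b.avo < b.avc < b.mvo <= b.end

    def test_deterministic_repetition(self):
        ps = nominal_parameters()
        a = simulate(ps, n_beats=4)
        b = simulate(ps, n_beats=4)
        assert np.array_equal(a.states, b.states)
        assert a.qrs == b.qrs

    def test_rejects_zero_beats(self):
        with pytest.raises(ValueError):
            simulate(nominal_parameters(), n_beats=0)

    def test_output_grid_is_uniform_milliseconds(self, healthy_sim):
        dt = np.diff(healthy_sim.t)
        assert np.allclose(dt, 1e-3, atol=1e-9)


class TestValveEvents:
    def test_square_wave_edges(self):
        ts = np.arange(0.0, 2.0, 1e-3)
        ys = np.zeros((ts.size, 18))
        xi_a = ((ts > 0.3) & (ts < 0.6)) | ((ts > 1.3) & (ts < 1.6))
        xi_m = (ts < 0.25) | ((ts > 0.7) & (ts < 1.25)) | (ts > 1.7)
        ys[:, 15] = xi_a.astype(float)
        ys[:, 14] = xi_m.astype(float)
        beats = detect_valve_events_arrays(ts, ys, [0.0, 1.0], 0.5)
        b = beats[0]
        assert b.mvc == pytest.approx(0.25, abs=2e-3)
        assert b.avo == pytest.approx(0.30, abs=2e-3)
        assert b.avc == pytest.approx(0.60, abs=2e-3)
        assert b.mvo == pytest.approx(0.70, abs=2e-3)

    def test_lower_threshold_gives_earlier_opening(self, healthy_sim):
        lo = detect_valve_events(healthy_sim, threshold=0.05)
        hi = detect_valve_events(healthy_sim, threshold=0.5)
        for a, b in zip(lo, hi):
            if a.complete and b.complete:
                assert a.avo < b.avo


class TestPressureGradient:
    def test_subtraction_identity(self, healthy_sim):
        assert pressure_gradient(healthy_sim) == pytest.approx(
            healthy_sim.p_lv_max - healthy_sim.pao_sys)

    def test_healthy_gradient_is_small(self, healthy_sim):
        assert pressure_gradient(healthy_sim) < 5.0

    def test_stenosis_raises_gradient(self, healthy_sim, stenotic_sim):
        assert pressure_gradient(stenotic_sim) > \
            pressure_gradient(healthy_sim) + 10.0


def test_solver_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(dt=-1.0)
    with pytest.raises(ValueError):
        SolverConfig(dt=1e-3, sample_dt=1e-4)


def test_heart_period_sets_cycle_length():
    ps = nominal_parameters(T=0.8)
    res = simulate(ps, n_beats=4)
    assert np.allclose(np.diff(res.qrs), 0.8, atol=1e-9)
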