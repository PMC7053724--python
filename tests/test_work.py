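import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cardiowork.work import (StrainSet, WorkIndices, compute_work_indices,
                             decompose_work, global_indices,
                             instantaneous_power, segmental_work)


def run_oracle(trace):
    """Brute-force monotone-run segmentation: walk the trace, cutting a run
    at every strict direction change, then total ascending increments and
    descending decrements run by run."""
    trace = np.asarray(trace, dtype=float)
    up = down = 0.0
    i = 0
    n = trace.size
    while i < n - 1:
        j = i
        if trace[j + 1] >= trace[j]:
            while j < n - 1 and trace[j + 1] >= trace[j]:
                j += 1
            up += trace[j] - trace[i]
        else:
            while j < n - 1 and trace[j + 1] <= trace[j]:
                j += 1
            down += trace[i] - trace[j]
        i = j
    return up, down


class TestInstantaneousPower:
    def test_constant_strain_gives_zero_power(self):
        t = np.linspace(0, 1, 101)
        power = instantaneous_power(t, np.full_like(t, -15.0),
                                    np.full_like(t, 100.0))
        assert np.allclose(power, 0.0)

    def test_zero_pressure_gives_zero_power(self):
        t = np.linspace(0, 1, 101)
        power = instantaneous_power(t, -20.0 * t, np.zeros_like(t))
        assert np.allclose(power, 0.0)

    def test_linear_shortening_hand_value(self):
        # strain falls linearly by 20% over 0.3 s at constant 100 mmHg:
        # raw product (d eps/dt) P = -6667 mmHg.%/s; the default
        # shortening-positive convention flips the sign
        t = np.linspace(0, 0.3, 301)
        strain = -20.0 / 0.3 * t
        p = np.full_like(t, 100.0)
        raw = instantaneous_power(t, strain, p, shortening_positive=False)
        assert np.allclose(raw, -20.0 / 0.3 * 100.0, rtol=1e-9)
        assert np.allclose(instantaneous_power(t, strain, p), 6666.7,
                           rtol=1e-4)

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_power(np.linspace(0, 1, 10), np.zeros(11),
                                np.zeros(10))


class TestSegmentalWork:
    def test_zero_power_zero_trace(self):
        t = np.linspace(0, 1, 101)
        _, w = segmental_work(t, np.zeros_like(t), 0.1, 0.9)
        assert np.allclose(w, 0.0)

    def test_constant_power_rectangle(self):
        t = np.linspace(0, 1, 1001)
        _, w = segmental_work(t, np.full_like(t, 5.0), 0.2, 0.8)
        assert w[-1] == pytest.approx(5.0 * 0.6, rel=1e-9)

    def test_full_sine_period_integrates_to_zero(self):
        t = np.linspace(0, 1, 4001)
        power = np.sin(2 * np.pi * (t - 0.2) / 0.6)
        _, w = segmental_work(t, power, 0.2, 0.8)
        assert abs(w[-1]) < 1e-6

    def test_events_outside_grid_rejected(self):
        t = np.linspace(0, 1, 101)
        with pytest.raises(ValueError):
            segmental_work(t, np.zeros_like(t), -0.5, 0.9)


class TestDecomposeWork:
    def test_run_boundary_example(self):
        # S-phase trace [0, 5, 3, 8]: ascending 0->5 and 3->8 (Wp=10),
        # descending 5->3 (Wn=2); flat IVR
        t = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
        w = np.array([0.0, 5.0, 3.0, 8.0, 8.0, 8.0])
        wp_s, wn_s, wp_ivr, wn_ivr = decompose_work(t, w, 0.0, 0.3, 0.5)
        assert (wp_s, wn_s) == (pytest.approx(10.0), pytest.approx(2.0))
        assert (wp_ivr, wn_ivr) == (0.0, 0.0)

    def test_single_run_phases(self):
        t = np.linspace(0, 1, 11)
        w = np.where(t <= 0.5, t, 1.0 - t) * 10
        wp_s, wn_s, wp_ivr, wn_ivr = decompose_work(t, w, 0.0, 0.5, 1.0)
        assert wn_s == 0.0
        assert wp_ivr == 0.0
        assert wp_s == pytest.approx(5.0)
        assert wn_ivr == pytest.approx(5.0)

    def test_flat_trace_all_zero(self):
        t = np.linspace(0, 1, 11)
        assert decompose_work(t, np.ones_like(t), 0.0, 0.5, 1.0) == \
            (0.0, 0.0, 0.0, 0.0)

    def test_random_traces_match_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 1, 41)
        for _ in range(200):
            w = rng.normal(0, 10, t.size).cumsum()
            wp_s, wn_s, wp_ivr, wn_ivr = decompose_work(t, w, 0.0, 0.5, 1.0)
            s = (t >= 0.0) & (t <= 0.5)
            r = (t >= 0.5) & (t <= 1.0)
            assert (wp_s, wn_s) == pytest.approx(run_oracle(w[s]))
            assert (wp_ivr, wn_ivr) == pytest.approx(run_oracle(w[r]))
            # telescoping identity: Wp - Wn equals the net phase change
            assert wp_s - wn_s == pytest.approx(w[s][-1] - w[s][0])
            assert wp_ivr - wn_ivr == pytest.approx(w[r][-1] - w[r][0])

    def test_time_reversal_swaps_ascending_and_descending(self):
        rng = np.random.default_rng(8)
        t = np.linspace(0, 0.5, 21)
        w = rng.normal(0, 5, t.size).cumsum()
        up, down = run_oracle(w)
        up_r, down_r = run_oracle(w[::-1])
        assert up_r == pytest.approx(down)
        assert down_r == pytest.approx(up)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(hnp.arrays(np.float64, st.integers(6, 60),
                      elements=st.floats(-50.0, 50.0)))
    def test_phase_totals_telescope_for_any_trace(self, w):
        """For any finite work trace, per-phase Wp - Wn equals the net
        change across that phase (the run partition telescopes)."""
        t = np.linspace(0.0, 1.0, w.size)
        mid = t[w.size // 2]
        if not (0.0 < mid < 1.0):
            return
        wp_s, wn_s, wp_ivr, wn_ivr = decompose_work(t, w, 0.0, mid, 1.0)
        s = t <= mid
        r = t >= mid
        assert wp_s - wn_s == pytest.approx(w[s][-1] - w[s][0], abs=1e-9)
        assert wp_ivr - wn_ivr == pytest.approx(w[r][-1] - w[r][0],
                                                abs=1e-9)
        assert min(wp_s, wn_s, wp_ivr, wn_ivr) >= 0.0

    def test_non_finite_samples_rejected(self):
        t = np.linspace(0, 1, 11)
        w = np.ones_like(t)
        w[3] = np.nan
        with pytest.raises(ValueError):
            decompose_work(t, w, 0.0, 0.5, 1.0)


class TestGlobalIndices:
    def test_single_segment_formula(self):
        w = global_indices([1500.0], [150.0], [0.0], [0.0])
        assert w.gcw == pytest.approx(1500.0)
        assert w.gww == pytest.approx(150.0)
        assert w.gwe == pytest.approx(1500.0 / 1650.0)

    def test_identical_segments_equal_global(self):
        w = global_indices([800.0] * 6, [40.0] * 6, [10.0] * 6, [90.0] * 6)
        assert w.gcw == pytest.approx(890.0)
        assert w.gww == pytest.approx(50.0)

    def test_efficiency_identity_and_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            comps = rng.uniform(0, 1000, size=(4, 5))
            w = global_indices(*comps)
            assert w.gwe == pytest.approx(w.gcw / (w.gcw + w.gww))
            assert 0.0 <= w.gwe <= 1.0

    def test_zero_total_work_flags_efficiency(self):
        w = global_indices([0.0], [0.0], [0.0], [0.0])
        assert np.isnan(w.gwe)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            WorkIndices(wp_s=np.array([-1.0]), wn_s=np.array([0.0]),
                        wp_ivr=np.array([0.0]), wn_ivr=np.array([0.0]))


class TestPipeline:
    def _strain_set(self, K=3, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1.0, 501)
        # shortening from MVC to AVC, lengthening back during IVR
        base = np.zeros_like(t)
        s = (t >= 0.05) & (t < 0.48)
        base[s] = -9.0 * (1 - np.cos(np.pi * (t[s] - 0.05) / 0.43))
        r = (t >= 0.48) & (t <= 0.70)
        base[r] = -9.0 * (1 + np.cos(np.pi * (t[r] - 0.48) / 0.22))
        strain = np.tile(base[:, None], (1, K))
        strain += rng.normal(0, noise, strain.shape)
        return StrainSet(t=t, strain=strain, mvc=0.05, avo=0.10,
                         avc=0.48, mvo=0.70)

    def _pressure(self, t):
        return 10.0 + 110.0 * np.exp(-0.5 * ((t - 0.3) / 0.13) ** 2)

    def test_synchronous_shortening_is_fully_constructive(self):
        ss = self._strain_set()
        w = compute_work_indices(ss, self._pressure(ss.t))
        assert w.gww < 0.01 * w.gcw
        assert w.gwe > 0.99

    def test_efficiency_invariant_to_pressure_rescaling(self):
        ss = self._strain_set(noise=0.3, seed=4)
        w1 = compute_work_indices(ss, self._pressure(ss.t))
        w2 = compute_work_indices(ss, 3.7 * self._pressure(ss.t))
        assert w2.gcw == pytest.approx(3.7 * w1.gcw, rel=1e-9)
        assert w2.gwe == pytest.approx(w1.gwe, rel=1e-9)

    def test_strain_grid_mismatch_rejected(self):
        ss = self._strain_set()
        with pytest.raises(ValueError):
            compute_work_indices(ss, self._pressure(ss.t)[:-1])
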