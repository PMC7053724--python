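import warnings

import numpy as np
import pytest

from cardiowork.cohort import (DyssynchronyConfig, NoiseConfig,
                               degrade_to_observables, read_patient_dir,
                               sample_patient, synth_strain,
                               write_patient_dir)
from cardiowork.parameters import X_LV_NAMES, get_param, nominal_parameters
from cardiowork.work import compute_work_indices

QUIET = NoiseConfig(sigma_plv=0.0, sigma_pao=0.0, sigma_ava=0.0,
                    sigma_strain=0.0)


@pytest.fixture(scope="module")
def patient():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return sample_patient("vpA", 13, severity=0.85)


class TestSamplePatient:
    def test_seed_reproducibility(self, patient):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            again = sample_patient("vpA", 13, severity=0.85)
        assert np.array_equal(patient.record.p_lv, again.record.p_lv)
        assert patient.record.pao_sys == again.record.pao_sys
        assert np.array_equal(patient.record.strain.strain,
                              again.record.strain.strain)

    def test_zero_jitter_keeps_nominal_truth(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vp = sample_patient("vpB", 3, severity=0.9, param_jitter=0.0)
        nom = nominal_parameters()
        for name in X_LV_NAMES:
            assert get_param(vp.truth, name) == get_param(nom, name)
        assert vp.ava == 0.9
        assert get_param(vp.truth, "valves.aortic.A_max") == 0.9

    def test_record_ava_matches_truth_area(self, patient):
        assert patient.record.ava == pytest.approx(patient.ava)

    def test_severity_controls_gradient(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tight = sample_patient("s1", 5, severity=0.75,
                                   param_jitter=0.0, noise=QUIET)
            wide = sample_patient("s2", 5, severity=2.5,
                                  param_jitter=0.0, noise=QUIET)
        assert tight.sim.delta_p > wide.sim.delta_p + 10.0

    def test_jitter_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sample_patient("bad", 0, param_jitter=0.5)


class TestDegradeToObservables:
    def test_noise_free_observables_equal_truth(self, patient):
        rec = degrade_to_observables("x", patient.sim, patient.ava,
                                     noise=QUIET,
                                     rng=np.random.default_rng(0))
        assert rec.pao_sys == pytest.approx(patient.sim.pao_sys)
        assert rec.pao_dias == pytest.approx(patient.sim.pao_dias)
        t_rel, p_true, _ = (patient.sim.t[patient.sim.analysis_slice]
                            - patient.sim.t[patient.sim.analysis_slice][0],
                            patient.sim.pressures["lv"][
                                patient.sim.analysis_slice], None)
        assert rec.p_lv == pytest.approx(
            np.interp(rec.t, t_rel, p_true), abs=1e-9)

    def test_sampling_rate(self, patient):
        rec = degrade_to_observables("x", patient.sim, patient.ava,
                                     noise=QUIET,
                                     rng=np.random.default_rng(0))
        assert np.allclose(np.diff(rec.t), 1.0 / 200.0)

    def test_aortic_noise_magnitude(self, patient):
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(300):
            rec = degrade_to_observables("x", patient.sim, patient.ava,
                                         rng=rng, K=1)
            errs.append(rec.pao_sys - patient.sim.pao_sys)
        assert np.std(errs) == pytest.approx(2.0, abs=0.4)

    def test_pressure_ordering_maintained_after_noise(self, patient):
        rng = np.random.default_rng(1)
        noisy = NoiseConfig(sigma_pao=30.0)    # extreme noise
        for _ in range(50):
            rec = degrade_to_observables("x", patient.sim, patient.ava,
                                         noise=noisy, rng=rng, K=1)
            assert rec.pao_sys > rec.pao_dias > 0


class TestSynthStrain:
    def test_single_clean_segment_shape(self, patient):
        ss = synth_strain(patient.sim, K=1,
                          rng=np.random.default_rng(0),
                          amplitude_sd=0.0, noise_sd=0.0)
        eps = ss.strain[:, 0]
        # near zero at MVC, minimum during ejection (between AVO and AVC)
        i_mvc = np.argmin(np.abs(ss.t - ss.mvc))
        assert abs(eps[i_mvc]) < 1.0
        i_min = np.argmin(eps)
        assert ss.avo < ss.t[i_min] <= ss.mvo
        assert eps.min() < -10.0

    def test_dyssynchrony_strictly_increases_wasted_work(self, patient):
        sl = patient.sim.analysis_slice
        t_rel = patient.sim.t[sl] - patient.sim.t[sl][0]
        p_true = patient.sim.pressures["lv"][sl]
        sync = synth_strain(patient.sim, K=12,
                            rng=np.random.default_rng(9),
                            amplitude_sd=0.0, noise_sd=0.0)
        dys = synth_strain(patient.sim, K=12,
                           rng=np.random.default_rng(9),
                           amplitude_sd=0.0, noise_sd=0.0,
                           dyssynchrony=DyssynchronyConfig(
                               fraction=0.5, max_shift_ms=60.0))
        w_sync = compute_work_indices(sync, np.interp(sync.t, t_rel,
                                                      p_true))
        w_dys = compute_work_indices(dys, np.interp(dys.t, t_rel, p_true))
        assert w_dys.gww > w_sync.gww
        assert w_dys.gwe < w_sync.gwe

    def test_invalid_segment_count(self, patient):
        with pytest.raises(ValueError):
            synth_strain(patient.sim, K=0)


class TestPatientIO:
    def test_directory_roundtrip(self, patient, tmp_path):
        d = write_patient_dir(patient.record, tmp_path / "vpA")
        back = read_patient_dir(d)
        assert back.patient_id == patient.record.patient_id
        assert back.pao_sys == pytest.approx(patient.record.pao_sys)
        assert back.ava == pytest.approx(patient.record.ava)
        assert back.p_lv == pytest.approx(patient.record.p_lv)
        assert back.strain.strain == pytest.approx(
            patient.record.strain.strain)
        assert back.strain.mvc == pytest.approx(patient.record.strain.mvc)
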