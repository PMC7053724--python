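"""Virtual aortic-stenosis patients with known ground truth.

Each virtual patient is a full closed-loop simulation whose parameters are
drawn around the nominal set (the identified ventricular and circulatory
parameters are jittered, the aortic effective area is the sampled stenosis
severity).  The hidden truth is then degraded to exactly the observables a
clinical workup provides: a catheter-rate LV pressure trace with additive
noise, noisy systolic/diastolic aortic readings, the valve area (AVA) and
K segmental longitudinal strain traces with the valve event times.

Segmental strain is synthesised from the true LV volume via a cube-root
self-similarity surrogate, eps(t) = 100 ((V(t)/V(MVC))^(1/3) - 1), then
per-segment amplitude-scaled, optionally time-shifted (dyssynchrony) and
noised.  The default cohort mirrors a severe-AS study population: 12
patients, 11 with AVA <= 1.0 cm^2 and one moderate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .identification import PatientRecord
from .parameters import (X_ART_NAMES, X_LV_NAMES, ParameterSet, get_param,
                         nominal_parameters, set_param)
from .simulator import SimulationError, SimulationResult, simulate
from .work import StrainSet, WorkIndices, compute_work_indices

__all__ = [
    "NoiseConfig",
    "DyssynchronyConfig",
    "VirtualPatient",
    "sample_patient",
    "degrade_to_observables",
    "synth_strain",
    "generate_cohort",
    "write_patient_dir",
    "read_patient_dir",
]

JITTERED_NAMES = X_LV_NAMES + X_ART_NAMES


@dataclass
class NoiseConfig:
    """Measurement-degradation settings (defaults emulate catheter + cuff).

    plv_rate_hz   catheter-like LV pressure sampling rate.
    sigma_plv     additive Gaussian noise on the LV trace (mmHg).
    sigma_pao     noise on the systolic/diastolic aortic readings (mmHg).
    sigma_ava     noise on the reported valve area (cm^2).
    sigma_strain  noise on each strain sample (%).
    """

    plv_rate_hz: float = 200.0
    sigma_plv: float = 1.0
    sigma_pao: float = 2.0
    sigma_ava: float = 0.0
    sigma_strain: float = 0.5


@dataclass
class DyssynchronyConfig:
    """Per-segment time shifts emulating mechanical dispersion.

    A ``fraction`` of segments is delayed by shifts drawn uniformly in
    [0, max_shift_ms]; the rest stay synchronous.
    """

    fraction: float = 0.5
    max_shift_ms: float = 60.0


@dataclass
class VirtualPatient:
    """Ground truth plus the derived observable record."""

    patient_id: str
    truth: ParameterSet
    ava: float
    sim: SimulationResult
    record: PatientRecord
    true_work: WorkIndices | None = None
    jitter_factors: dict[str, float] = field(default_factory=dict)


def _true_beat(sim: SimulationResult) -> tuple[np.ndarray, np.ndarray,
                                               np.ndarray]:
    """(t_rel, P_lv, V_lv) of the analysis beat, t = 0 at its QRS."""
    sl = sim.analysis_slice
    t = sim.t[sl]
    return t - t[0], sim.pressures["lv"][sl], sim.volume("lv")[sl]


def synth_strain(sim: SimulationResult, K: int = 18,
                 rng: np.random.Generator | None = None,
                 amplitude_sd: float = 0.05,
                 noise_sd: float = 0.5,
                 dyssynchrony: DyssynchronyConfig | None = None,
                 grid: np.ndarray | None = None) -> StrainSet:
    """K segmental strain traces from the true LV volume of the analysis
    beat, with valve events copied from the simulation.

    Segment k applies an amplitude scale ~N(1, amplitude_sd), an optional
    dyssynchronous time shift (periodic) and additive Gaussian noise.
    """
    if K < 1:
        raise ValueError("need K >= 1 segments")
    rng = rng or np.random.default_rng()
    t_rel, _, v = _true_beat(sim)
    beat = sim.analysis_beat
    if not beat.complete:
        raise SimulationError("analysis beat lacks valve events")
    t0 = beat.start
    mvc = beat.mvc - t0
    base_grid = t_rel if grid is None else np.asarray(grid, dtype=float)
    v_on = np.interp(base_grid, t_rel, v)
    v_mvc = np.interp(mvc, t_rel, v)
    eps_base = 100.0 * (np.cbrt(v_on / v_mvc) - 1.0)

    shifts = np.zeros(K)
    if dyssynchrony is not None:
        n_shift = int(round(dyssynchrony.fraction * K))
        shifts[:n_shift] = rng.uniform(0.0, dyssynchrony.max_shift_ms / 1e3,
                                       size=n_shift)
    scales = np.clip(rng.normal(1.0, amplitude_sd, size=K), 0.5, 1.5)
    period = t_rel[-1]
    strains = np.empty((base_grid.size, K))
    for k in range(K):
        shifted = np.mod(base_grid - shifts[k], period)
        strains[:, k] = scales[k] * np.interp(shifted, base_grid, eps_base)
        if noise_sd > 0:
            strains[:, k] += rng.normal(0.0, noise_sd, size=base_grid.size)
    return StrainSet(t=base_grid, strain=strains,
                     mvc=mvc, avo=beat.avo - t0,
                     avc=beat.avc - t0, mvo=beat.mvo - t0)


def degrade_to_observables(patient_id: str, sim: SimulationResult,
                           ava: float,
                           noise: NoiseConfig | None = None,
                           rng: np.random.Generator | None = None,
                           K: int = 18,
                           dyssynchrony: DyssynchronyConfig | None = None
                           ) -> PatientRecord:
    """Derive the clinical observables of one patient from its simulated
    truth: resampled/noised LV pressure, noised aortic readings, (optional)
    noised AVA and the synthetic strain set on the same grid."""
    noise = noise or NoiseConfig()
    rng = rng or np.random.default_rng()
    t_rel, p_lv, _ = _true_beat(sim)
    t_c = float(t_rel[-1])
    grid = np.arange(0.0, t_c, 1.0 / noise.plv_rate_hz)
    p = np.interp(grid, t_rel, p_lv)
    if noise.sigma_plv > 0:
        p = p + rng.normal(0.0, noise.sigma_plv, size=grid.size)
    pao_sys = sim.pao_sys + rng.normal(0.0, noise.sigma_pao)
    pao_dias = sim.pao_dias + rng.normal(0.0, noise.sigma_pao)
    # enforce the record invariant (sys > dias > 0) after noise
    pao_dias = max(pao_dias, 5.0)
    pao_sys = max(pao_sys, pao_dias + 2.0)
    ava_obs = ava + (rng.normal(0.0, noise.sigma_ava)
                     if noise.sigma_ava > 0 else 0.0)
    strain = synth_strain(sim, K=K, rng=rng, noise_sd=noise.sigma_strain,
                          dyssynchrony=dyssynchrony, grid=grid)
    return PatientRecord(patient_id=patient_id, t=grid, p_lv=p,
                         pao_sys=float(pao_sys), pao_dias=float(pao_dias),
                         ava=float(max(ava_obs, 0.1)), t_c=t_c,
                         strain=strain)


def sample_patient(patient_id: str,
                   rng: np.random.Generator | int | None = None,
                   severity: float | tuple[float, float] = (0.6, 1.0),
                   param_jitter: float = 0.15,
                   T_range: tuple[float, float] = (0.85, 1.05),
                   noise: NoiseConfig | None = None,
                   K: int = 18,
                   dyssynchrony: DyssynchronyConfig | None = None,
                   n_beats: int = 12,
                   max_retries: int = 5) -> VirtualPatient:
    """Draw one virtual patient.

    The identified parameters (X_LV and X_art) are jittered uniformly
    within +/-param_jitter around nominal; the aortic A_eff_max is the
    sampled severity (AVA).  Draws whose simulation diverges are resampled
    (bounded retries).
    """
    if not (0.0 <= param_jitter <= 0.3):
        raise ValueError("param_jitter must lie in [0, 0.3]")
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    last_err: Exception | None = None
    for _ in range(max_retries):
        ava = (float(severity) if np.isscalar(severity)
               else float(rng.uniform(*severity)))
        ps = nominal_parameters(T=float(rng.uniform(*T_range)))
        factors = {}
        for name in JITTERED_NAMES:
            f = 1.0 + rng.uniform(-param_jitter, param_jitter)
            factors[name] = f
            set_param(ps, name, get_param(ps, name) * f)
        set_param(ps, "valves.aortic.A_max", ava)
        set_param(ps, "valves.aortic.A_min", 0.001 * ava)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sim = simulate(ps, n_beats=n_beats)
            record = degrade_to_observables(patient_id, sim, ava,
                                            noise=noise, rng=rng, K=K,
                                            dyssynchrony=dyssynchrony)
        except (SimulationError, ValueError) as err:
            last_err = err
            continue
        # work from the patient's own (true) pressure and observed strain
        t_rel, p_true, _ = _true_beat(sim)
        p_on_strain = np.interp(record.strain.t, t_rel, p_true)
        true_work = compute_work_indices(record.strain, p_on_strain)
        return VirtualPatient(patient_id=patient_id, truth=ps, ava=ava,
                              sim=sim, record=record, true_work=true_work,
                              jitter_factors=factors)
    raise SimulationError(
        f"could not draw a stable virtual patient after {max_retries} "
        f"retries: {last_err}")


def generate_cohort(n: int = 12, seed: int = 0,
                    n_moderate: int = 1,
                    severe_range: tuple[float, float] = (0.6, 1.0),
                    moderate_range: tuple[float, float] = (1.2, 1.5),
                    param_jitter: float = 0.15,
                    noise: NoiseConfig | None = None,
                    K: int = 18,
                    dyssynchrony: DyssynchronyConfig | None = None
                    ) -> list[VirtualPatient]:
    """A reproducible virtual cohort: ``n - n_moderate`` severe patients
    (AVA <= 1 cm^2) plus ``n_moderate`` moderate ones."""
    ss = np.random.SeedSequence(seed)
    patients = []
    for i, child in enumerate(ss.spawn(n)):
        sev = severe_range if i < n - n_moderate else moderate_range
        patients.append(sample_patient(
            f"vp{i + 1:02d}", np.random.default_rng(child), severity=sev,
            param_jitter=param_jitter, noise=noise, K=K,
            dyssynchrony=dyssynchrony))
    return patients


# ---------------------------------------------------------------------------
# on-disk patient layout (plv.csv, obs.json, strain.csv, events.json)
# ---------------------------------------------------------------------------

def write_patient_dir(record: PatientRecord, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": record.t, "pressure_mmhg": record.p_lv}
                 ).to_csv(d / "plv.csv", index=False)
    (d / "obs.json").write_text(json.dumps({
        "patient_id": record.patient_id,
        "pao_sys": record.pao_sys, "pao_dias": record.pao_dias,
        "ava_cm2": record.ava, "t_c": record.t_c,
    }, indent=1))
    if record.strain is not None:
        s = record.strain
        df = pd.DataFrame(s.strain,
                          columns=[f"seg{k + 1:02d}"
                                   for k in range(s.n_segments)])
        df.insert(0, "time_s", s.t)
        df.to_csv(d / "strain.csv", index=False)
        (d / "events.json").write_text(json.dumps({
            "MVC": s.mvc, "AVO": s.avo, "AVC": s.avc, "MVO": s.mvo,
        }, indent=1))
    return d


def read_patient_dir(directory) -> PatientRecord:
    d = Path(directory)
    plv = pd.read_csv(d / "plv.csv")
    obs = json.loads((d / "obs.json").read_text())
    strain = None
    if (d / "strain.csv").exists():
        sdf = pd.read_csv(d / "strain.csv")
        ev = json.loads((d / "events.json").read_text())
        strain = StrainSet(
            t=sdf["time_s"].to_numpy(),
            strain=sdf.drop(columns="time_s").to_numpy(),
            mvc=ev["MVC"], avo=ev["AVO"], avc=ev["AVC"], mvo=ev["MVO"])
    return PatientRecord(
        patient_id=str(obs.get("patient_id", d.name)),
        t=plv["time_s"].to_numpy(), p_lv=plv["pressure_mmhg"].to_numpy(),
        pao_sys=obs["pao_sys"], pao_dias=obs["pao_dias"],
        ava=obs["ava_cm2"], t_c=obs["t_c"], strain=strain)
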