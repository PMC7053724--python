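"""Two-step patient-specific parameter identification.

Step 1 (training, invasive): for each training patient the ventricular and
circulatory parameter sets {X_LV, X_art} are jointly identified by
minimising

    J_step1 = J_PLV + J_Pao,sys + J_Pao,dias

where J_PLV is the mean absolute error between the measured and simulated
LV pressure over one cardiac cycle (synchronised on the QRS marker) and the
aortic terms are absolute errors on the systolic/diastolic readings.  The
ventricular parameters are then frozen at their training-set average
X_LV_bar.

Step 2 (test, non-invasive): only {X_art} is identified from the aortic
pressure readings, J_step2 = J_Pao,sys + J_Pao,dias, and the LV pressure
curve is *predicted* by the model.  The aortic valve area (AVA) is never
identified: A_eff_max of the aortic valve is fixed to the measured AVA.

Both minimisations use a real-coded evolutionary algorithm (differential
evolution: mutation, recombination, survivor selection) within +/-30%
bounds around nominal values.  A Monte-Carlo cross-validation loop draws N
random half/half train/test splits and averages the per-patient work
markers over the iterations in which each patient was tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution

from .metrics import total_relative_error
from .parameters import (X_ART_NAMES, X_LV_NAMES, ParameterSet, get_param,
                         nominal_parameters, set_param)
from .simulator import (SimulationError, SimulationResult, SolverConfig,
                        simulate)
from .work import StrainSet, WorkIndices, compute_work_indices

__all__ = [
    "PatientRecord",
    "CostBreakdown",
    "EAConfig",
    "ea_minimize",
    "cost_step1",
    "cost_step2",
    "simulate_candidate",
    "run_step1",
    "run_step2",
    "monte_carlo_cross_validation",
    "IdentificationResult",
]

_PENALTY = 1.0e6


@dataclass
class PatientRecord:
    """Observables of one (real or virtual) patient.

    The LV pressure trace is one cardiac cycle, uniformly sampled, with
    t = 0 at the QRS fiducial.  ``strain`` may be None when only pressure
    estimation is of interest.
    """

    patient_id: str
    t: np.ndarray               # (n,), seconds, from the QRS
    p_lv: np.ndarray            # (n,), mmHg
    pao_sys: float
    pao_dias: float
    ava: float                  # cm^2
    t_c: float                  # cycle length, s
    strain: StrainSet | None = None
    qrs_time: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p_lv = np.asarray(self.p_lv, dtype=float)
        if self.t.shape != self.p_lv.shape:
            raise ValueError("time and pressure grids differ")
        if self.t_c <= 0:
            raise ValueError("cycle length must be > 0")
        if not (self.pao_sys > self.pao_dias > 0):
            raise ValueError("need Pao_sys > Pao_dias > 0")
        if self.ava <= 0:
            raise ValueError("AVA must be > 0")


@dataclass
class CostBreakdown:
    """Components of the identification cost (all mmHg, all >= 0)."""

    j_plv: float
    j_pao_sys: float
    j_pao_dias: float

    @property
    def j_step1(self) -> float:
        return self.j_plv + self.j_pao_sys + self.j_pao_dias

    @property
    def j_step2(self) -> float:
        return self.j_pao_sys + self.j_pao_dias


@dataclass
class EAConfig:
    """Evolutionary-minimisation settings.

    population    individuals per generation.
    generations   maximum generations.
    stall_generations  stop early when the best cost has not improved (by
                  ``stall_tol`` relative) for this many generations.
    n_beats       cardiac cycles integrated per candidate evaluation.
    """

    population: int = 50
    generations: int = 60
    stall_generations: int = 15
    stall_tol: float = 1.0e-4
    mutation: tuple[float, float] = (0.3, 0.9)
    recombination: float = 0.8
    n_beats: int = 8

    def __post_init__(self) -> None:
        self.mutation = tuple(self.mutation)
        if self.population < 5:
            raise ValueError("population must be >= 5")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


def ea_minimize(cost_fn, bounds, ea_cfg: EAConfig | None = None,
                seed: int | np.random.Generator = 0
                ) -> tuple[np.ndarray, list[float]]:
    """Minimise ``cost_fn`` over box ``bounds`` with a seeded evolutionary
    algorithm.

    Returns the best parameter vector and the best-so-far cost history
    (one entry per generation, non-increasing).  Reproducible for a fixed
    seed.
    """
    cfg = ea_cfg or EAConfig()
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    if any(hi <= lo for lo, hi in bounds):
        raise ValueError("invalid bounds")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    dims = len(bounds)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    init = lo + (hi - lo) * rng.random((max(cfg.population, 5), dims))
    history: list[float] = []
    stall = {"best": np.inf, "count": 0}
    n_fail = 0
    best_seen = [np.inf]

    def guard(x):
        nonlocal n_fail
        try:
            v = float(cost_fn(np.asarray(x, dtype=float)))
        except SimulationError:
            n_fail += 1
            v = _PENALTY
        if not np.isfinite(v):
            n_fail += 1
            v = _PENALTY
        best_seen[0] = min(best_seen[0], v)
        return v

    def record(xk, convergence=None):  # noqa: ARG001 - scipy callback API
        best = best_seen[0]
        history.append(best)
        if best < stall["best"] * (1.0 - cfg.stall_tol):
            stall["best"] = best
            stall["count"] = 0
        else:
            stall["count"] += 1
        return stall["count"] >= cfg.stall_generations

    res = differential_evolution(
        guard, bounds, init=init, maxiter=cfg.generations,
        mutation=cfg.mutation, recombination=cfg.recombination,
        seed=rng, tol=0.0, polish=False, callback=record,
        updating="immediate",
    )
    if not history:
        history = [min(float(res.fun), best_seen[0])]
    if n_fail > 0 and res.fun >= _PENALTY:
        raise RuntimeError("all evolutionary evaluations failed")
    return np.asarray(res.x, dtype=float), history


# ---------------------------------------------------------------------------
# cost functions
# ---------------------------------------------------------------------------

def model_lv_trace(result: SimulationResult,
                   record: PatientRecord) -> np.ndarray:
    """Model LV pressure of the analysis beat resampled onto the patient's
    sampling grid, QRS-aligned."""
    t_rel, p = result.beat_pressure("lv")
    return np.interp(np.mod(record.t - record.qrs_time, record.t_c),
                     t_rel, p)


def cost_step1(result: SimulationResult,
               record: PatientRecord) -> CostBreakdown:
    """J_PLV (cycle mean absolute LV-pressure error) plus the two aortic
    reading errors."""
    p_model = model_lv_trace(result, record)
    j_plv = float(np.mean(np.abs(record.p_lv - p_model)))
    return CostBreakdown(
        j_plv=j_plv,
        j_pao_sys=abs(record.pao_sys - result.pao_sys),
        j_pao_dias=abs(record.pao_dias - result.pao_dias),
    )


def cost_step2(result: SimulationResult,
               record: PatientRecord) -> CostBreakdown:
    """Aortic reading errors only (the non-invasive cost); the LV trace
    plays no role."""
    return CostBreakdown(
        j_plv=0.0,
        j_pao_sys=abs(record.pao_sys - result.pao_sys),
        j_pao_dias=abs(record.pao_dias - result.pao_dias),
    )


def simulate_candidate(record: PatientRecord, names, values,
                       base: ParameterSet | None = None,
                       n_beats: int = 8,
                       solver: SolverConfig | None = None
                       ) -> SimulationResult:
    """Simulate one parameter candidate under the patient's constraints:
    heart period = measured cycle length, aortic A_eff_max = measured AVA."""
    ps = (base or nominal_parameters()).copy()
    ps.T = record.t_c
    ps.electrical = None
    set_param(ps, "valves.aortic.A_max", record.ava)
    set_param(ps, "valves.aortic.A_min", 0.001 * record.ava)
    for n, v in zip(names, values, strict=True):
        set_param(ps, n, float(v))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return simulate(ps, n_beats=n_beats, solver=solver)


def _bounds_around(base: ParameterSet, names,
                   fraction: float = 0.30) -> list[tuple[float, float]]:
    out = []
    for n in names:
        v = get_param(base, n)
        lo, hi = v * (1 - fraction), v * (1 + fraction)
        out.append((min(lo, hi), max(lo, hi)))
    return out


# ---------------------------------------------------------------------------
# the two identification steps
# ---------------------------------------------------------------------------

@dataclass
class PatientFit:
    """Identified parameters and fit quality for one patient in one run."""

    patient_id: str
    names: tuple[str, ...]
    x_best: np.ndarray
    cost_history: list[float]
    cost: CostBreakdown
    p_lv_model: np.ndarray
    e_percent: float
    work: WorkIndices | None = None


def _fit_patient(record: PatientRecord, names, base: ParameterSet,
                 step_cost, ea_cfg: EAConfig, seed) -> PatientFit:
    bounds = _bounds_around(base, names)

    def cost(x):
        res = simulate_candidate(record, names, x, base=base,
                                 n_beats=ea_cfg.n_beats)
        return step_cost(res, record).j_step1  # step2 sets j_plv = 0

    x_best, history = ea_minimize(cost, bounds, ea_cfg, seed)
    res = simulate_candidate(record, names, x_best, base=base,
                             n_beats=ea_cfg.n_beats)
    p_model = model_lv_trace(res, record)
    e_pct = total_relative_error(record.p_lv, p_model,
                                 record.pao_sys, res.pao_sys,
                                 record.pao_dias, res.pao_dias)
    work = None
    if record.strain is not None:
        p_on_strain = np.interp(record.strain.t, record.t, p_model)
        work = compute_work_indices(record.strain, p_on_strain)
    return PatientFit(patient_id=record.patient_id, names=tuple(names),
                      x_best=x_best, cost_history=history,
                      cost=step_cost(res, record), p_lv_model=p_model,
                      e_percent=e_pct, work=work)


def run_step1(records, ea_cfg: EAConfig | None = None,
              base: ParameterSet | None = None,
              seed: int | np.random.SeedSequence = 0
              ) -> tuple[dict[str, PatientFit], np.ndarray]:
    """Joint {X_LV, X_art} identification on the training patients.

    Returns per-patient fits and the element-wise training average
    X_LV_bar.  Patients whose simulations diverge are flagged and excluded
    from the average.
    """
    records = list(records)
    cfg = ea_cfg or EAConfig()
    base = base or nominal_parameters()
    names = X_LV_NAMES + X_ART_NAMES
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    fits: dict[str, PatientFit] = {}
    x_lv_list = []
    for record, child in zip(records, ss.spawn(len(records))):
        try:
            fit = _fit_patient(record, names, base, cost_step1, cfg,
                               np.random.default_rng(child))
        except RuntimeError as err:
            warnings.warn(f"patient {record.patient_id} excluded from "
                          f"step 1: {err}", RuntimeWarning, stacklevel=2)
            continue
        fits[record.patient_id] = fit
        x_lv_list.append(fit.x_best[:len(X_LV_NAMES)])
    if not x_lv_list:
        raise RuntimeError("no training patient could be identified")
    return fits, np.mean(x_lv_list, axis=0)


def run_step2(records, x_lv_bar: np.ndarray,
              ea_cfg: EAConfig | None = None,
              base: ParameterSet | None = None,
              seed: int | np.random.SeedSequence = 0
              ) -> dict[str, PatientFit]:
    """{X_art} identification on the test patients with the ventricle
    frozen at X_LV_bar; emits the predicted LV pressure per patient."""
    records = list(records)
    cfg = ea_cfg or EAConfig()
    base = (base or nominal_parameters()).with_values(X_LV_NAMES, x_lv_bar)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    fits: dict[str, PatientFit] = {}
    for record, child in zip(records, ss.spawn(len(records))):
        try:
            fit = _fit_patient(record, X_ART_NAMES, base, cost_step2, cfg,
                               np.random.default_rng(child))
        except RuntimeError as err:
            warnings.warn(f"patient {record.patient_id} excluded from "
                          f"step 2: {err}", RuntimeWarning, stacklevel=2)
            continue
        fits[record.patient_id] = fit
    return fits


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation
# ---------------------------------------------------------------------------

@dataclass
class IdentificationResult:
    """Cross-validation output: per-split fits and per-patient averaged
    markers (means over the iterations in which the patient was tested)."""

    splits: list[tuple[list[str], list[str]]]
    x_lv_bar: list[np.ndarray]
    step1_fits: list[dict[str, PatientFit]]
    step2_fits: list[dict[str, PatientFit]]
    averaged: dict[str, dict[str, float]] = field(default_factory=dict)

    def test_fits(self, patient_id: str) -> list[PatientFit]:
        return [fits[patient_id] for fits in self.step2_fits
                if patient_id in fits]


def monte_carlo_cross_validation(
    cohort, n_realizations: int = 10,
    ea_step1: EAConfig | None = None,
    ea_step2: EAConfig | None = None,
    base: ParameterSet | None = None,
    seed: int = 0,
) -> IdentificationResult:
    """N random half/half train/test splits; step 1 on training, step 2 on
    test; work markers (GCW/GWW/GWE) averaged per patient over its test
    appearances.

    All randomness (splits and both EA stages) derives from the master
    ``seed``.
    """
    cohort = list(cohort)
    if len(cohort) < 2:
        raise ValueError("cohort must have >= 2 patients")
    if n_realizations < 1:
        raise ValueError("need >= 1 realization")
    ea_step1 = ea_step1 or EAConfig()
    ea_step2 = ea_step2 or EAConfig(population=30, generations=30)
    ss = np.random.SeedSequence(seed)
    split_rng = np.random.default_rng(ss.spawn(1)[0])
    result = IdentificationResult(splits=[], x_lv_bar=[], step1_fits=[],
                                  step2_fits=[])
    half = len(cohort) // 2
    for n in range(n_realizations):
        order = split_rng.permutation(len(cohort))
        train = [cohort[i] for i in order[:half]]
        test = [cohort[i] for i in order[half:]]
        s1_seed, s2_seed = ss.spawn(2)
        fits1, x_lv_bar = run_step1(train, ea_step1, base, s1_seed)
        fits2 = run_step2(test, x_lv_bar, ea_step2, base, s2_seed)
        result.splits.append(([r.patient_id for r in train],
                              [r.patient_id for r in test]))
        result.x_lv_bar.append(x_lv_bar)
        result.step1_fits.append(fits1)
        result.step2_fits.append(fits2)

    never_tested = {r.patient_id for r in cohort}
    for fits in result.step2_fits:
        never_tested -= set(fits)
    if never_tested:
        warnings.warn(f"patients never in a test set: {sorted(never_tested)}"
                      " — increase N", RuntimeWarning, stacklevel=2)

    for record in cohort:
        fits = result.test_fits(record.patient_id)
        if not fits:
            continue
        entry: dict[str, float] = {
            "e_percent": float(np.mean([f.e_percent for f in fits])),
            "n_test": float(len(fits)),
        }
        works = [f.work for f in fits if f.work is not None]
        if works:
            entry["gcw_model"] = float(np.mean([w.gcw for w in works]))
            entry["gww_model"] = float(np.mean([w.gww for w in works]))
            entry["gwe_model"] = float(np.mean([w.gwe for w in works]))
        result.averaged[record.patient_id] = entry
    return result
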