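# Methods

## Model overview

`cardiowork` implements a closed-loop lumped-parameter model of the
cardiovascular system for studying aortic stenosis (AS), together with a
patient-specific estimation pipeline for left-ventricular (LV) pressure and
the pressure–strain myocardial work indices computed from it.

The model couples four sub-models:

1. **Cardiac electrical activity** — seven coupled finite-state automata
   (sinoatrial node NSA, atria RA/LA, atrioventricular node NAV, upper
   bundle of His UH, ventricles RV/LV).  Each automaton cycles through slow
   diastolic depolarisation (SDD), upstroke depolarisation (UDP), absolute
   (ARP) and relative (RRP) refractory phases, emits an activation at the
   end of UDP and stimulates its neighbours after a conduction delay.  The
   NSA is the only pacemaker; its four phase durations sum to the heart
   period T.  Ventricular activation instants serve as QRS markers; each
   activation resets the clock of the corresponding mechanical driver.
   The automata network is simulated event-wise (priority queue), exactly
   and deterministically; the resulting activation times are handed to the
   continuous integrator as driver reset times.
2. **Cardiac cavities** — ventricular pressure blends the linear
   end-systolic relation E_es (V − V_d) and the exponential end-diastolic
   relation P_0 (exp(λ(V − V_0)) − 1) through a double-Hill driver
   e(t) = k · [(t/α₁T)ⁿ¹ / (1+(t/α₁T)ⁿ¹)] · [1 / (1+(t/α₂T)ⁿ²)].
   k is *derived*, not free: it normalises the driver so max e = 1, making
   E_es the true maximal elastance (the driver-scale reading of k is
   ambiguous otherwise, and the identified ventricular set contains the
   four shape parameters but not k).  Atria use a linear elastance driven
   by a Gaussian bump E(t) = E_max exp(−B(t−C)²) + E_min; the literal peak
   is E_max + E_min, and a `peak_convention="max"` switch is provided.
3. **Circulation** — six vessel chambers (aorta, systemic artery, systemic
   vein, vena cava, pulmonary artery, pulmonary vein), each a linear
   elastance reservoir P = E (V − V_d), joined by Ohmic resistances.  The
   loop is LV → aortic valve → ao −R_ao→ sa −R_sys→ sv −R_vc→ vc −R_ra→
   RA → tricuspid → RV → pulmonary valve → pa −R_pul→ pv −R_pv→ LA →
   mitral → LV.  The vena-cava-to-right-atrium resistance R_ra is needed to
   close the chain of finite resistances; it is small and is not part of
   the identified circulatory set.  Volume bookkeeping is pure
   conservation, so total blood volume is constant up to solver error.
4. **Valves** — all four valves follow a Bernoulli + inertance law
   ΔP = B Q|Q| + L dQ/dt with B = ρ/(2A_eff²), L = ρ l_eff/A_eff, and a
   first-order opening law dξ/dt = (1−ξ)K_vo ΔP (ΔP>0) or ξ K_vc ΔP
   (ΔP≤0), with A_eff = (A_max − A_min)ξ + A_min.  A_min defaults to
   0.1% of A_max — a negligible leak that keeps B finite when closed.
   Units: pressures mmHg, flows mL/s, areas cm², blood density 1.06 g/cm³;
   the single CGS→mmHg conversion (1333.22 dyn/cm² per mmHg) happens at
   coefficient construction.  Aortic stenosis is represented by reducing
   the aortic A_max; during identification the aortic A_max is always
   fixed to the patient's measured valve area (AVA) and never identified.

## Numerics

The 18 coupled states (10 volumes, 4 valve flows, 4 opening fractions) are
integrated with a fixed-step classical Runge–Kutta scheme compiled with
numba.  The fastest time scale is the valve rate law (K·|ΔP| up to roughly
2·10³ 1/s with the default rate constants), which sets the default step
dt = 0.25 ms; output is sampled on a uniform 1 ms grid, matching catheter
sampling scales.  ξ ∈ [0,1] boundaries are invariant manifolds of the
exact flow; the O(dt⁵) discretisation overshoot is clipped.  The EDPVR
exponent is capped at 40 so that exploratory (far out-of-range) parameter
draws fail gracefully instead of overflowing.  A pure-Python reference
right-hand side mirrors the compiled kernel and the test suite checks the
two against each other on random states.

Simulations run beat by beat (beats delimited by LV activations) from a
physiologic initial state (volumes near unstressed values, the
systemic-vein chamber absorbing the remainder of the configured total
blood volume; valves closed and flowless).  Periodic steady state is
declared when consecutive beats agree in peak LV pressure and stroke
volume to within 0.5%; analyses use the last beat.  Default runs use 15
beats; identification evaluations use 8 (steady to well within the
beat-to-beat tolerance in practice).  Valve events (MVC/AVO/AVC/MVO) are
read from ξ crossings of a 0.05 threshold with linear interpolation.

## Nominal parameters

The nominal parameter set was calibrated once so that the healthy
simulation (aortic A_max = 2.5 cm²) reproduces textbook AS-study
hemodynamics — systolic LV pressure ≈ 120 mmHg with aortic pressure
spanning ≈ 50–120 mmHg — and then frozen; the stenotic run
(A_max = 0.75 cm², LV ≈ 150 mmHg over aorta ≈ 110 mmHg) is a pure
prediction of the model, not a separate calibration.  Double-Hill shape
defaults (α₁ = 0.303, α₂ = 0.508, n₁ = 1.32, n₂ = 21.9) are the classic
normalised-elastance values.  All parameters are config-exposed.

## Myocardial work

Segmental power is strain rate times instantaneous LV pressure with the
clinical sign convention (shortening against pressure counts positive), so
the cumulative work w(t) = ∫ −(dε/dt) P dt ascends during effective
systolic shortening.  Work is accumulated from mitral valve closure to
mitral valve opening, split at aortic valve closure into systole (S) and
isovolumic relaxation (IVR), and each phase is partitioned into maximal
monotone runs: Wp sums ascending increments, Wn descending magnitudes
(ties within 1e-12 continue the current run, and the run partition
telescopes so Wp − Wn equals the net phase change exactly).  Then
GCW = mean_k(Wp_S + Wn_IVR), GWW = mean_k(Wn_S + Wp_IVR),
GWE = GCW/(GCW+GWW).  Strain is differentiated by central differences with
no pre-smoothing (smoothing changes the Wp/Wn split; the transparent
estimator is the default).  Work is reported in mmHg·%.

## Sensitivity screening

Morris elementary effects: one-at-a-time trajectories on a 4-level grid in
the unit hypercube with step Δ = 2/3, mapped to ±30% physical ranges
around nominal; r = 10 trajectories by default.  μ* is the mean absolute
effect; σ is the standard deviation of the *signed* effects (revised-
Morris convention; a flag computes it over |EE| instead); parameters are
ranked by the distance D = √(μ*² + σ²).  The screened output is the
transvalvular gradient ΔP = max(P_LV) − Pao_sys.  The default operating
point sets the aortic area to 1.0 cm² (the severe-AS boundary): around a
healthy valve the gradient is ~1 mmHg and nearly parameter-insensitive,
so the screening question — what shapes the gradient in the stenotic
regime of an AS cohort — is only answerable there.  At that point the
aortic area dominates, with LV end-systolic elastance and the relaxation
shape parameter α₂ among the top parameters.

## Identification

Two steps, embedded in Monte-Carlo cross-validation:

* **Step 1 (invasive, training)** jointly identifies X_LV = {E_es, λ, P_0,
  α₁, α₂, n₁, n₂} and X_art = {E_ao, E_vc, E_sa, E_sv, Vd_ao, Vd_vc,
  Vd_sa, Vd_sv, R_ao, R_sys, R_vc} per training patient by minimising
  J₁ = mean|P_LV^exp − P_LV^model| + |ΔPao_sys| + |ΔPao_dias| (the LV term
  is the per-sample mean absolute error over one QRS-aligned cycle, which
  equals the 1/T_c-normalised sum up to the fixed grid).  The ventricular
  set is then frozen at the training average X̄_LV.
* **Step 2 (non-invasive, test)** identifies X_art only, from
  J₂ = |ΔPao_sys| + |ΔPao_dias|, and predicts the LV pressure curve.

Bounds are ±30% around nominal (the same convention as the sensitivity
ranges).  The simulator's heart period is set to the patient's measured
cycle length and the aortic A_max to the measured AVA.  Minimisation uses
differential evolution (a real-coded evolutionary algorithm: mutation,
recombination, greedy survivor selection), seeded, without polishing, with
an early stop after 15 stalled generations; defaults are population 50 ×
60 generations, and the packaged experiments use reduced budgets (30×30
for single-patient recovery, 18×16 / 14×14 inside cross-validation) chosen
as the smallest budgets that leave a wide margin on the recovery
tolerances.  Failed simulations score a large penalty.  Cross-validation
draws N half/half train/test splits (default N = 10; the packaged cohort
experiment uses N = 3) and averages each patient's predicted work markers
over the iterations in which it was tested.  One master seed drives the
splits and every EA stage through spawned seed sequences.

## Synthetic cohort

Virtual patients stand in for clinical recordings: ground truth is a full
simulation whose identified parameters are jittered uniformly (default
±15%) around nominal, heart period drawn in 0.85–1.05 s, and stenosis
severity (AVA = aortic A_max) drawn in 0.6–1.0 cm² (11 of 12 patients;
one moderate patient at 1.2–1.5 cm²).  Observables are degraded to what a
catheter-and-cuff workup provides: LV pressure resampled at 200 Hz with
1 mmHg Gaussian noise, aortic readings with 2 mmHg noise, AVA (noise-free
by default), and K = 18 segmental strains.  Strain is synthesised from the
true LV volume by the cube-root self-similarity surrogate
ε(t) = 100((V(t)/V(MVC))^{1/3} − 1) — the simplest mapping yielding
physiologic strain shapes from a lumped (regionless) ventricle — with
per-segment amplitude scales ~N(1, 0.05), optional dyssynchronous time
shifts and 0.5% additive noise.  What passing recovery tests show is that
the pipeline inverts the model class it assumes under realistic noise;
they cannot show robustness to structural mismatch (real ventricles are
not the model), to imaging artefacts, or to strain morphologies beyond
amplitude/shift/noise perturbations.

## Known limitations

No ventricular interaction, baroreflex, respiratory modulation or
regurgitation (beyond the closed-valve leak); valve rate constants and
conduction timings are fixed, not identified; the regression/Bland–Altman
module reports per-cohort agreement without confidence intervals.
Identifiability is practical, not structural: distinct parameter sets can
produce near-identical pressures, so recovery is asserted on the pressure
curve and derived work indices, not on individual parameter values.
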