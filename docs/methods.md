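# Methods

## Model structure and assumptions

`hpolsim` integrates a deterministic, stiff ODE description of the female
rainbow trout reproductive axis over one or more annual cycles.  The
structural assumptions are:

* **Clearance–volume pharmacokinetics.**  Every circulating species
  (FSH, LH, E2, DHP, VTG) has a plasma-referenced volume of distribution
  `V_i` (ml/kg) and a first-order clearance `Cl_i` (ml/hr/kg).  VTG
  additionally exchanges reversibly with a peripheral pool through a
  transfer clearance.
* **Transit-compartment delays.**  Signal-transduction lags are Erlang
  chains of `m` first-order compartments with per-compartment rate `m/D`,
  so the impulse response has mean exactly `D` hours.  Three delays are
  published: FSH→E2 (875 h), E2→mLH (240 h), LH→DHP (72 h).  The number
  of compartments per chain is a configuration knob (default `m = 5`,
  a smooth lag without adding stiffness); it is not a fitted quantity.
* **Threshold feedbacks** are Hill terms; hard switches use the unit
  step with `U(0) = 0` (the convention the LH release derivation
  requires; note many libraries default to `U(0) = ½`).
* **Dopamine-gated LH release.**  Pituitary LH is released as the
  spillover `max(Θ,0)·H₊(E2, T_E2,LH, 9)` with
  `Θ = LH_Pit − N_E2·E2 − N_DHP·DHP`.  Because the release constant
  `k_r,LH ≈ 6.7e4 hr⁻¹` dwarfs every other rate, the store is pinned at
  the block level whenever the gate is open: release episodes are
  periods when E2 *declines* relative to its own ~36-day-lagged history.
  This single mechanism produces both the premature LH rise and the
  pre-ovulatory surge.  An alternative stage-restricted release
  (`(S₆+S_FOM)·H₋(E2)·LH_Pit`) is selectable via
  `SimulationOptions(release_function="stage_gated")`.
* **Weibull oocyte staging.**  The clutch's diameter distribution is the
  Weibull with mean `O_Avg` (a state) and variance `O_Var` (algebraic).
  Stage masses are CDF increments between the fixed boundaries
  s₁…s₆; stage 1 occupies [0, s₁] and FOM everything above s₆.  `O_Var`
  is the stage-weighted mixture of per-stage maximal variances, which
  couples it to the stage masses; the pair is resolved as a damped fixed
  point in the variance (tolerance 1e-9, damping 0.5).
* **E2 stage sum.**  E2 production sums stages 2–6 only (FOM oocytes do
  not synthesise E2), while DHP production includes FOM.  The narrative
  "stages 2 through FOM" and the E2 balance disagree on this point; the
  package follows the balance equation.  The consequence — E2 collapses
  as the clutch enters FOM — is precisely what opens the LH gate at the
  right moment.
* **Ovulation and reset.**  Ovulation is the first simultaneous crossing
  of `DHP ≥ DHP_final` (120 ng/ml) and `S_FOM ≥ FOM_final` (0.98),
  detected by the integrator's event root-finding on
  `min(DHP − DHP_final, S_FOM − FOM_final)`.  Twenty-one days later
  `O_Avg` alone is reset to its cycle-start value (0.15 mm); all hormone
  states continue.  Whether anything else should reset between cycles is
  genuinely open; the reset set is configurable but defaults to the
  single documented reset.

Parameters (79 entries: synthesis/degradation rates, clearances,
volumes, stage boundaries in mm, stage variances in mm², thresholds,
delays) live in `hpolsim.parameters` with units and the original symbol
recorded per field; `data/parameters.tsv` is the same registry as a
shareable table.  `O_Avg` is treated as a diameter in mm throughout (one
published table prints "mm/kg", but every figure and equation uses mm).

## The packaged GnRH programme

GnRH is the only exogenous forcing and is not observable; the published
model derived it empirically from pituitary mFSH measurements that are
not available in printed form.  The packaged default is therefore a
parametric annual programme — baseline 6 plus three Gaussian pulses
(centre day, width, amplitude): (112, 45, 142), (188, 24, 136),
(295, 28, 102) — calibrated once, during package development, so the
baseline simulation reproduces the documented cycle-level behaviour:
ovulation inside the 345–365 day window, a mid-cycle FSH wave of
~5–11 ng/ml, late-cycle E2 maxima trailing FSH maxima by the FSH→E2
delay, a premature LH rise ~2.5 months before the main surge, and a
maximum mean diameter satisfying (s₆−s₂)/max O_Avg ≈ 0.84.  The pulse
coefficients are frozen constants, not tunables of the analysis.

The programme's period is 380 days: the ~357-day cycle plus the
three-week post-spawn reset.  With a 365-day period each successive
cycle starts ~2 weeks later in seasonal phase and by the third cycle the
clutch misses the late-season window in which E2 is still above the LH
release gate — the axis then parks in a non-reproductive state.  The
380-day period phase-locks successive cycles (equal spacing over
multi-year runs).  Users fitting real populations should replace the
default with a tabulated driver recovered from their own FSH series
(`calibrate_gnrh_from_fsh`), which inverts the two linear balances
connecting FSH to GnRH through cubic-spline differentiation and clips
negative excursions to zero.

## Numerics

* **Integrator**: `scipy.integrate.solve_ivp` with LSODA (stiff-capable,
  as the system demands), `rtol = 1e-6` and a per-state absolute
  tolerance vector scaled to each state's typical magnitude (mVTG spans
  1e6 while stage-era FSH is order 1).  Halving both tolerances moves
  the predicted ovulation time by well under half a day (asserted in the
  acceptance tests).  Output is recorded on a fixed hourly grid
  regardless of internal steps.
* **Staging table.**  The variance fixed point and moment-matched
  Weibull depend only on `O_Avg` once boundaries and stage variances are
  fixed, so `simulate()` tabulates them once per parameter set on a
  1400-point diameter grid (0.02–10 mm) and interpolates scale, shape
  and variance with cubic splines inside the right-hand side.  Stage
  masses are then exact Weibull probabilities of the interpolated
  distribution — non-negative and summing to one by construction — and
  agree with the exact fixed point to better than 1e-6 (tested).  This
  removes all root-finding from the hot path; a full one-cycle run takes
  a couple of seconds on one CPU.
* **Weibull moment inversion** solves the CV–shape relation by bracketed
  root-finding on log k over k ∈ [0.05, 500] (the CV is strictly
  monotone in the shape, so convergence is guaranteed); inputs whose CV
  falls outside that bracket raise, except in staging where the CV is
  clamped — a vanishing-variance clutch behaves as a point mass.
* **Spillover regularisation.**  `Θ·U(Θ)` is computed as `max(Θ, 0)`
  (identical values, one-sided derivative); LSODA handles the resulting
  mildly non-smooth right-hand side without event chatter because the
  steep Hill gate (n = 9) dominates the transition.
* **Non-negativity** is enforced weakly: hormone inputs to production
  terms are clipped at zero inside the right-hand side, and trajectories
  are asserted to stay above −10·atol.

## Sensitivity analysis

The PAWN implementation collapses a run to the scalar
`Σ_f ‖f_alt − f_base‖₂ / ‖f_base‖₂` over the 15 primary trajectories on
the hourly grid (variables with zero reference norm are skipped with a
warning).  Parameter boxes are ±20% around the published values, sampled
with scrambled Sobol' sequences; draws violating structural invariants
(stage-boundary ordering) are rejected and replaced.  The index is the
median (optionally max) Kolmogorov–Smirnov distance between the
unconditional output CDF and the conditional CDFs at
evenly-spaced conditioning quantiles.  Defaults
(`N_u = 200, n_c = 5, N_c = 40`) are desk-scale screening sizes;
reproducing a full 79-parameter published-scale ranking is a batch
computation and the exact rank order is sample-size dependent — only
directional dominance (E2/VTG synthesis and oocyte-growth parameters
over, e.g., LH pharmacokinetics) should be expected to be stable.

## Synthetic observations

`make_synthetic_series` samples simulated trajectories at a realistic
cadence (default biweekly) with multiplicative lognormal noise, and is
what the calibration and fitting tests consume — no external data set is
required anywhere.  These fixtures emulate assay sampling schedules and
proportional measurement error; they do *not* emulate inter-individual
variability, cohort effects, assay detection limits or within-day
pulsatility, so green tests demonstrate self-consistency of the
machinery, not field validity.

## Reduced VTG model

The full hepatic cascade can be swapped for a single delayed-E2
production term into plasma VTG
(`SimulationOptions(vtg_model="simplified")`, E2→VTG delay 100 h).  The
gain `k_E2,VTG` has no published value; the packaged default (220) was
chosen on the baseline run to reproduce the full model's plasma-VTG
*peak timing* (within days) and ovulation time (within ~4 days).  The
peak *magnitude* of the reduced model runs ~⅓ lower: the full model's
transient post-FOM VTG spike is amplified by the liver reservoir and the
γ power law, which a single linear gain cannot represent.  Matching the
spike height instead requires a gain that ovulates months early;
trajectory fidelity was preferred.

## Stressor scenarios

The trenbolone scenario multiplies stage-4/5 E2 secretion clearances by
0.54 in every variant, quadruples `k_s,FSH` while the clutch is
majority pre-vitellogenic (gate: S₁+S₂ ≥ 0.5, smoothed over a 0.05 band
to keep the right-hand side continuous — the exposure literature reports
the FSH effect in pre-vitellogenic fish, and the smooth gate avoids
solver restarts), and per variant adds `Cl_E2 × 1.41` and/or
`k_s,mVTG × 0.6`.  Scenario application composes with ordinary parameter
perturbations and is order-independent on disjoint parameter sets.

## Known limitations

* **Synthesis-only trenbolone variant.**  In this calibration the
  46% stage-4/5 E2-synthesis reduction alone already postpones ovulation
  into the following season, rather than leaving the cycle essentially
  intact.  The cause is structural: early stage-4 E2 is produced by the
  small stage-5 tail of the diameter distribution, so mid-cycle E2 sits
  in the unsaturated regime of the hepatic receptor cascade, where the
  γ = 2.48 translational power law turns a ~2× E2 reduction into a ~3×
  VTG reduction and stalls vitellogenic growth past the seasonal window.
  Making mid-cycle E2 receptor-saturated would require implausibly high
  FSH.  The corresponding acceptance test is left failing by design; the
  augmented variants' reproductive failure (the quantitative claim) is
  reproduced.
* Kisspeptin regulation of GnRH, gonadotropin receptor dynamics,
  individual-follicle tracking, next-cycle oogonia recruitment and
  spawning behaviour itself are outside the model, as in the published
  formulation.
* Late-cycle DHP and VTG excursions are larger than typical assay
  values; ovulation timing depends only on threshold crossings, not on
  the excursion heights.
* The auxiliary dopamine-receptor quantities (ξ, [D2r]) of the release
  derivation are absorbed into `N_E2`, `N_DHP` and have no runtime
  representation.
* The mapping from gonadosomatic index to mean diameter is not included;
  users with GSI data must supply their own regression when building
  observed series.
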