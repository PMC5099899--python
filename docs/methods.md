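# Methods

## Model structure and assumptions

The model describes a C-peptide-negative type-1-diabetes patient on pump
therapy during a mixed-meal test. Three deliberate simplifications define
its scope:

* **No endogenous insulin.** All insulin enters through the pump: a
  constant basal subcutaneous infusion and a square-pulse meal bolus feed a
  single subcutaneous depot that drains into one plasma compartment
  (volume `V_I`, clearance `CL_I`) with rate constant `1/mtt_ins`. The
  depot mean transit time `mtt_ins` is the reported insulin MTT.
* **One accessible glucose pool, fluxes not concentrations.** Glucose mass
  `Q` in a pool of volume `V_G` is drained by (a) a fixed utilization
  `F_b` of 1 mg/kg/min, representing insulin-independent (mostly brain)
  uptake, and (b) a clearance `S_G + X` acting on the concentration, where
  `S_G` is glucose effectiveness and `X` the classic remote insulin action
  driven by the excursion of insulin above basal (`dX/dt = p_2(S_I(I−I_b)
  − X)`). `S_I` is a *net* sensitivity: without tracers the effects of
  insulin on utilization and on residual endogenous production cannot be
  separated.
* **Basal closure.** A constant glucose input `EGB = F_b + S_G·G_b/1000`
  exactly balances the basal drains, so a patient started at `(G_b, X=0)`
  with the basal insulin level stays at steady state indefinitely. `EGB`
  is of the order of endogenous glucose production but is an instrument of
  closure, not a measurement of it.

Oral absorption is two parallel Erlang chains — fast (2 compartments, rate
`k_fast`) and slow (4 compartments, `k_slow`) — fed by a square ingestion
pulse of recorded duration `T_ing` delayed by `t_lag`; a fraction `phi`
takes the fast route. The summed terminal efflux is the oral glucose input
(OGI). The chain orders are fixed so the OGI keeps exactly three free
parameters while still producing the characteristic one/two-peaked shape
with exponential decay; the dose entering the chains is
`f_bio·c_ge·carb_g` grams of glucose equivalents with bioavailability
`f_bio = 0.9` and `c_ge = 1.0` g/g, both fixed constants (the meal
carbohydrate content must be known exactly). By construction the OGI
time-integral equals the bioavailable dose, so the model cannot invent or
destroy meal glucose.

Initial conditions `D_0`, `G_0`, `X_0` are estimated (a real patient need
not be at steady state at meal time), completing the 16-entry estimation
vector. Units: glucose mmol/l, insulin pmol/l, fluxes mmol/min; `S_G` and
`S_I` are reported as clearances (ml/min and (ml/min)/(pmol/l)) and
converted with the molar mass of glucose, 180.156 g/mol; 1 U of insulin is
6000 pmol.

## Parameters that matter

| parameter | units | canonical value | why it matters |
|---|---|---|---|
| `S_I` | (ml/min)/(pmol/l) | 0.78 | net insulin sensitivity; the clinically central quantity |
| `S_G` | ml/min | 20.8 | insulin-independent glucose clearance |
| `mtt_ins` | min | 112 | s.c. depot transit; sets the bolus action profile |
| glucose MTT | min | 117 (292 kcal), 109 (600 kcal) | gut-to-blood transit of the meal |
| `p_2` | 1/min | 0.02 | delay of insulin action |
| `V_G`, `V_I` | ml, l | 11200, 9 | distribution volumes (≈0.16 l/kg and ≈0.13 l/kg at 70 kg) |
| `CL_I` | l/min | 1.1 | insulin clearance; fixes basal insulin at `basal_rate/CL_I` |

The canonical virtual patient carries these values with `phi = 0.7`,
`t_lag = 10` min and chain rates solved so the glucose MTT is exactly 117
min under the 292 kcal protocol (38.9 g carbohydrate, 10-min ingestion,
bolus by an insulin-to-carbohydrate ratio of 10 g/U, 70 kg, 1.8 m², basal
100 pmol/min ⇒ basal insulin ≈ 91 pmol/l). These magnitudes are standard
physiology for adult pump-treated T1D; the double meal scales the
carbohydrate load proportionally (79.9 g at 600 kcal).

## Estimation

The objective stacks SD-weighted data residuals (glucose block then
insulin block) with prior penalties `w_j(θ_j − μ_j)/μ_j` and is minimized
by the bound-constrained trust-region-reflective algorithm at tolerance
1e-10. The prior set for a study combines:

* **clamp**: `S_I` prior from the simulated (or measured) hyperinsulinemic
  euglycemic clamp, weight 10 — the anchor that makes the otherwise
  degenerate `S_I`/`S_G`/absorption trade-off identifiable;
* **patient-specific**: `G_b` and `I_b` priors at the pre-meal sample
  means, weight 5 — they pin the basal closure (without them the optimizer
  can construct spurious quasi-basal configurations with inflated `G_b`
  compensated by initial action);
* **literature**: `V_I`, `CL_I`, `V_G`, `p_2` (weight 5) and `S_G`,
  `k_fast`, `k_slow` (weight 2) at typical values — weakly identifiable
  kinetic constants that a five-hour two-analyte study cannot determine
  alone.

Bounds default to [0.1×, 10×] of the typical magnitudes, with
physiological exceptions: `phi ∈ [0.01, 0.99]`, `t_lag ∈ [0, 60]` min,
`X_0 ∈ [0, 10]` ml/min (the protocol prescribes an overnight steady
state), `G_b, G_0 ∈ [3, 20]` mmol/l, and `k_slow ≥ 0.012`/min so the slow
chain completes absorption within ≈5.5 h — data sampled for 300 min carry
no information about slower tails, and leaving them unbounded lets meal
mass escape beyond the observation window and inflates the fitted transit
time.

Multi-start search: a data-informed central start (typical values, prior
means, basal levels read off the pre-meal samples) plus a scrambled Sobol
dispersion over the bounds (log-spaced for scale parameters). All starts
are screened by initial cost; the best 6 receive a full local
optimization and the lowest total SSR wins. The Sobol sequence is
prefix-stable, so enlarging the start set can only improve the best
objective, and everything is bit-reproducible from the seed.

## Numerical choices

Inside the objective the ODE system is integrated by a compiled fixed-step
classic Runge–Kutta (step ≤ 0.5 min) whose knots include every input
discontinuity (bolus edges, ingestion onset/offset) and every observation
time, so model predictions are exact nodal values and the objective is
smooth for finite-difference Jacobians. The public `simulate` offers an
adaptive RK45 reference (rtol 1e-8, atol 1e-10, integrated piecewise
between discontinuities); the two paths agree to ~4e-8 relative on the
canonical meal and the agreement is asserted in the test suite. Finite
differences use a relative step of 1e-5; optimizer and simulation are
fully deterministic.

Degenerate inputs are rejected eagerly (non-positive rates/volumes, zero
SDs, non-increasing times, clamp with `I_ss ≤ I_b`); near-equal depot and
plasma rate constants need no special casing because integration is
numerical throughout.

## The simulated clamp

Insulin is delivered intravenously into the plasma compartment (0.8 U/m²
prime over 5 min, then 40 mU/min/m²) while the subcutaneous basal analogue
is assumed to keep contributing its baseline influx. A discrete
proportional–integral controller (gains 3.0 and 0.2, 5-min updates,
anti-windup) adjusts the dextrose infusion to hold glucose at 5.0 mmol/l;
the M-value is the mean infusion over the final 60 min of a 240-min clamp,
valid only if glucose stayed within 5% of target there. The gains and
duration were chosen so the controller transient contributes negligibly to
M (glucose settles to within 0.1% of target); shorter, looser clamps bias
M several percent low. The derived prior
`S_I = M·BSA/(G_clamp·(I_ss − I_b))` still sits ~3–4% below the true
`S_I` by construction: at a clamp target below basal glucose the M-value
includes a negative `S_G·(G − G_b)` contribution. This definitional bias
is left in place — it is what a real clamp measures.

## The virtual-patient generator

The generator emulates the study conditions: the 292 kcal standardized
meal and its 600 kcal double, a 16-point sampling schedule (−20…300 min,
denser around the excursion onset), multiplicative Gaussian measurement
noise with 2% CV on glucose (duplicate bedside measurement) and 6% on
insulin (ELISA scale), with SD columns reflecting the noise actually
applied. Population draws are independent mean-preserving log-normals per
parameter (logit-normal for `phi`); day-to-day within-subject variability
is log-normal with the scale calibrated by √π so that the two-point CV
estimator `|θ₁−θ₂|/√2 / mean` is unbiased for the nominal CV.

What the generator does **not** emulate: model mismatch (real physiology
is not the model), correlated or heteroscedastic assay error beyond the
CV model, intra-day parameter drift, meal-composition effects (fat and
protein are ignored beyond the carbohydrate count), insulin-analog
differences, or interstitial-glucose dynamics. Passing recovery tests
therefore demonstrates that the pipeline is consistent and well calibrated
under the model's own assumptions — not that the model is correct for any
real patient.

## Residual calibration and degrees of freedom

With a correctly specified model and noise, weighted residuals should be
zero-mean with unit scale. Because each fit absorbs roughly
`p_eff ≈ 10` of the 32 residual degrees of freedom (the trace of the
prior-penalized hat matrix; priors keep it well below the raw 16), the
*raw* pooled residual SD of a perfect pipeline sits near
`√(1 − p_eff/N) ≈ 0.82`, not 1. The calibration study therefore reports
the reduced scale `√(Σ SSR / Σ(N − p_eff))`, which lands at 0.93–1.01
across seeds; per-fit diagnostics keep the plain population-SD convention
and flag `|mean| > 0.5` or SD outside [0.5, 2] as misfit.

## Reference studies and problem sizes

The validation studies run 5 noise replicates × 20-start fits for each
meal size and 20 replicates × 5-start fits for the calibration study —
about 30 complete multi-start identifications, a scale chosen so the full
suite re-runs in well under a minute while the replicate means are stable
to a few percent. Recovered means across many seeds: `S_I` −3 to −4%
(dominated by the definitional clamp bias), `S_G` within ±5%, insulin MTT
within ±5%, glucose MTT −3 to +13% (right-skewed: the 300-min window is
weakly informative about the slow-absorption tail, and `1/k` convexity
maps symmetric rate noise into asymmetric transit-time noise).

## Known limitations

* `S_I` estimates inherit the clamp definitional bias (a few percent low);
  users wanting the pure model optimum can lower `si_weight` or disable
  priors entirely, at the cost of conditioning.
* The glucose-MTT estimator is right-skewed under sparse 300-min sampling;
  cohort means based on few replicates can run ~10% high.
* The slow-chain lower bound (absorption complete within ≈5.5 h) is an
  identifiability constraint, not a measurement; studies of
  slowly-absorbed meals would need a longer sampling window and a relaxed
  bound.
* No population (mixed-effects) estimation, no Bayesian posteriors, no
  identifiability profiling beyond the recovery suite, no CGM error model.
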