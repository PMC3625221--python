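# Methods

## Models

All three model variants are linear stage-structured transmission models for
the invasion phase of an epidemic: the susceptible pool is held at its
initial value S0, so incidence follows a renewal equation whose kernel ψ(τ)
(rate of secondary transmission at infection-age τ per infected individual)
integrates to R0 and whose discounted integral gives the Euler–Lotka
growth-rate relation ∫ψ(τ)e^(−rτ)dτ = 1.

**Symptom-based model.**  Stages are defined by what surveillance can see:
an asymptomatic stage entered at infection (transmission rate β_A(τ), onset
rate η(τ), recovery rate γ_A(τ)) and a symptomatic stage entered at onset
(β_S(σ), recovery γ_S(σ), σ = disease-age).  Reduced forms:
R1 = ∫β_A·exp(−∫(η+γ_A)), α = ∫η·exp(−∫(η+γ_A)) (a competing-risk
probability, so α ∈ [0,1] automatically), R2 = ∫β_S·exp(−∫γ_S), and
R0 = R1 + α·R2.  θ = R1/R0 is the asymptomatic share of transmission.

**Contagiousness-based (SEIR-type) model.**  Stages are defined by
infectiousness: latency E (exit rate ε(τ)), then symptomatic or asymptomatic
infectious with probability k / (1−k), recovery rates κ_S, κ_A, transmission
β(τ) scaled by m ≤ 1 for asymptomatic cases.  R4 = ∫β·P_S, R3 = m·∫β·P_A
(P_X = probability of occupying stage X at infection-age τ), and
R0 = k·R4 + (1−k)·R3.  The symptom probability k weights the symptomatic
term; this is the only weighting consistent with the α = k matching
condition and with the calibrated threshold equality used throughout.
Likewise m is defined as R3/R4 (asymptomatic relative to symptomatic, ≤ 1).

**Bridge model.**  The symptom-based model's asymptomatic stage decomposed
into pre-symptomatic H_S (transmitting at β_H, onset at η/α — scaled because
the symptomatic fate is assigned at infection), asymptomatic non-infectious
H_A (→ I at rate ρ) and asymptomatic infectious I (m·β, exit ζ_A).  With
R_a, R_pre the per-class expected secondary cases,
R0 = (1−α)·R_a + α·(R_pre + R2), and the bookkeeping identities
α·R_pre = g·θ·R0 and (1−α)·R_a = (1−g)·θ·R0 define the pre-symptomatic
share g and close the parameter set.  Setting g = 0 (β_H ≡ 0) with matched
rates recovers the SEIR-type model; the checker verifies the three
consistency conditions (α = k; ε = η/α = ρ and β_H ≡ 0; recovery rates
identical constants) with a per-condition maximal deviation at tolerance
1e-9.  A non-constant recovery rate is reported as a structural failure of
condition (c) regardless of pointwise agreement, because the collapse onto
the SEIR-type model requires the system to reduce to ordinary differential
equations.

**Vaccination.**  Coverage p and three multiplicative efficacies
(VE_S, VE_I, VE_P with residuals q_S, q_I, q_D).  The 2×2 next-generation
matrix has rows = infectee stratum (unvaccinated first; susceptibility
weights (1−p) and p·q_S) and columns = infector stratum (q_I and q_D only in
the vaccinated column).  It is rank one by construction, so
R_v = trace = (1−p)A + p·q_S·q_I·B; the eigenvalue routine asserts
trace-equality internally whenever the matrix is numerically rank one.
Critical coverage is solved in closed form with three statuses: interior,
always_subcritical (A ≤ 1, p* = 0) and uncontrollable (q_S·q_I·B ≥ 1 with
A > 1; p* reported as NaN).  Waning, non-leaky vaccine action and
age/risk-structured vaccination are out of scope.

## Kernels and numerics

The table-driven analyses need only reduced forms; kernels are optional
mechanistic backing.  Rates default to constants (exponential stage
durations), which makes every reduced form closed form and gives the tests
exact oracles; piecewise-constant and Erlang-stage hazards are available for
sensitivity work.  Ages are continuous from the relevant event, grids
half-open [0, age_max) with default step 0.01 time units, and age_max is
chosen so the truncated survival mass is below 1e-10 (an absent absorbing
hazard raises a divergence error rather than truncating silently).

Cumulative hazards accumulate by the midpoint rule (exact for
piecewise-constant hazards with grid-aligned breaks); reproduction integrals
use the trapezoid rule on the survival grid; two-stage occupancies use a
second-order exponential-decay recursion that cannot overflow on long
grids.  All quadratures are second order, so the matched-configuration R0
equality between model families holds to ~1e-7 at grid step 0.001.
Grid mismatches between a survival curve and a requested step are resolved
by logged linear resampling, never silently.

## Linearized dynamics and synthetic data

`simulate_linear` advances cohort counts along characteristics (age grid =
time grid, exact transport, exact exponential within-step survival) with a
trapezoidal (Heun) treatment of the birth term: the new age-0 cohort's
same-step feedback on the force of infection is solved linearly, and every
cohort created within a step (births, stage transfers) carries a half-step
decay with its removed mass routed to the downstream stage.  This makes the
scheme second order in the step; growth-rate errors at the default step are
~3e-5 relative, and halving the step moves cumulative incidence by well
under 0.1%.  A step coarser than 0.5/max-hazard raises a stability error
with a suggested step.  Seeding is a unit pulse of age-0 infections at
t = 0 (size configurable).

The simulator is also the synthetic-data generator: the deterministic series
carry exactly the stage structure, kernels and parameter values of the
models (stage exit rates default to 1/time unit when matching a reduced
form — a simulation convention, since the reduced-form tables pin totals,
not durations).  The only randomness is an optional negative-binomial
observation overlay (mean-preserving, variance μ + μ²/dispersion,
dispersion default 10) governed by a single integer seed.  The generator
emulates surveillance-style incidence and onset series with overdispersed
counts; it does not emulate susceptible depletion, reporting delays,
day-of-week effects or contact heterogeneity, so passing tests certify the
internal consistency of the models, not their fit to any real outbreak.

Growth rates are fitted by least squares on log new infections over a
window defaulting to the last 40% of the horizon (skipping the seeding
transient); nonpositive values in the window are a domain error suggesting
a later window.  The Euler–Lotka root is found by Brent's method after
geometric bracket expansion (the residual is strictly decreasing in r).

## Fixtures

Fixture files are JSON, one object per disease:

```json
{
  "name": "influenza",
  "observable": {"R1": 0.6, "R2": 1.2, "alpha": 0.75},
  "R_a": 0.96, "g": 0.6, "theta": 0.4, "R0_printed": 1.5,
  "m_assumed": 0.5,
  "vaccine": {"VE_S": 0.41, "VE_I": 0.15, "VE_P": 0.67},
  "provenance": {"source": "...", "notes": "..."}
}
```

`m_assumed` is the relative asymptomatic infectiousness used when
calibrating the SEIR-type counterpart (0.5 for three diseases, 0.7 for
varicella — display conventions of the comparison, not estimates).

The four bundled parameter sets store printed 2-decimal values; validation
checks the closure identities (R0 recomposition, θ-closure, g-closure,
R_a-closure) at tolerances reflecting that precision: 0.015 for the R0
recomposition (two independent 2-dp roundings), 0.01 for θ·R0 = R1, 0.02
for the bridge closures.  Varicella's recomposed R0 is 6.48 against a
printed 6.47; all derived quantities use the recomposed value consistently.
HIV's g is stored as the exact fraction 2/3 (printed 0.67 kept in
provenance) and its vaccine efficacies are flagged hypothetical.  R_pre is
never printed; it is derived at load time from α·R_pre = g·θ·R0 and logged.
Tightening the validation tolerance to 1e-6 fails exactly the
rounding-affected entries, which documents the table's printed precision.

Along the g-sensitivity sweep, R_a and R_pre are held fixed as independent
inputs while α is re-derived from g; this reproduces the expected
monotonicity directions.  Varicella's sweep direction is not asserted
anywhere: its two competing weights (R_pre + R2 = 6.48 vs R_a = 6.47)
differ only in the last printed digit, so the slope's sign is a rounding
artifact.  Smallpox's and varicella's R_a values carry zero weight in the
baseline R0 (α = 1) and are exercised only by this sweep.

## Design choices and limitations

* Reduced-form construction is the primary entry path everywhere; kernels
  back it optionally.  Estimation of any parameter from data
  (backcalculation, fitting to incidence) is out of scope, as are
  heterogeneous contact structure and household models.
* The η/α onset scaling exists only inside the kernel-level bridge
  construction; reduced-form operations never see it.
* The VE_P axis is the user-facing sweep variable (q_D = 1 − VE_P derived
  internally); the model orderings asserted are invariant to flipping the
  axis.
* The CLI is a thin layer over the library; figure-reproduction commands
  emit data tables by default, with plotting behind an opt-in flag, so
  every artifact is byte-reproducible and testable.
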