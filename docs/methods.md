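# Methods

## Scope and model family

`pmxbayes` implements a Bayesian workflow for pharmacokinetic (PK) and
pharmacokinetic/pharmacodynamic (PK/PD) models driven by clinical event
schedules. The pieces are deliberately modular: an event-schedule engine,
interchangeable solvers (closed form, matrix exponential, adaptive
Runge–Kutta, and a one-way coupled PK/PD solver), a log-joint-density
assembly with bound-respecting parameter transforms, an adaptive
Hamiltonian Monte Carlo (HMC) sampler, and a checking layer
(rank-normalized R-hat and bulk/tail ESS, posterior predictive checks,
PSIS-LOO model comparison).

## Event schedules

Events follow the NONMEM data conventions: per row `time, amt, rate, ii,
addl, cmt, evid, ss`, plus `dv` on measurement rows. Only `evid` 0
(measurement) and 1 (dose) are defined; reset codes are rejected rather
than ignored so that silent semantic drift is impossible. `addl`
expansion materializes `k+1` identical doses at `t, t+ii, …, t+k·ii`.

Tie-breaking at shared timestamps is the part that decides what a
"predose" sample means, so it is pinned down and tested:

* records execute in input order at equal times; a dose row records the
  post-dose state, an observation row listed before a same-time dose
  records the pre-dose state;
* doses *generated* by `addl` expansion execute after same-time original
  records. A trough sample recorded at a repeat-dose time therefore reads
  the pre-dose concentration, which is what a predose sample is.

Lag times shift the dose *entry* only; the dose row itself still reports
the state at its nominal time, so an observation inside a lag window sees
the pre-absorption state. Bioavailability scales the administered amount;
an infusion of amount `amt` at rate `rate` therefore runs for
`F·amt/rate` hours at the stated rate.

## Linear PK solvers

The two-compartment model with first-order absorption is solved in closed
form by diagonalizing the rate matrix analytically: decay rates
`(ka, λ1, λ2)` with the hybrid rates the roots of
`λ² − (k10+k12+k21)λ + k10·k21` (the slow root is computed from the
product identity to avoid cancellation), and eigenvectors assembled from
the micro-constants. Constant zero-order inputs are handled exactly in
eigen-coordinates through `(1−e^{−λt})/λ`, with the `λ→0` limit taken
explicitly, so a conservative system (CL = 0) needs no matrix inversion.

Near-degenerate spectra — absorption rate within 1e-8 (relative) of a
hybrid rate, coincident hybrid rates, or `Q ≈ 0` (where the disposition
eigenvectors collapse) — fall back to a matrix-exponential propagator
(scipy's scaling-and-squaring Padé routine on the augmented matrix
`[[A, b], [0, 0]]`). One code path, no L'Hôpital branches.

Steady-state dosing (`ss=1`) solves the linear fixed point
`u* = e^{A·ii} u* + F·amt·e_cmt` for a bolus; infusions propagate the
zero-order segment inside one interval. A non-dissipative system is
rejected with "no steady state". `ss=1` combined with `addl` initializes
the first dose from the steady state; later copies propagate normally.
Dose rows report post-dose amounts — the convention needed so trough
observations listed before a dose row read the trough.

For likelihood evaluation there is also a vectorized superposition path
(sum of single-dose tri-exponential responses over a parameter batch),
valid for bolus-only, single-parameter-set, zero-initial-state schedules.
It is an implementation detail of speed, not semantics: it is tested to
1e-12 against the sequential solver, and batch rows it flags as
near-degenerate are recomputed by the general path.

## ODE engine

`integrate` wraps an adaptive embedded Runge–Kutta 4(5) stepper with the
standard `rtol`/`atol` local error control and an explicit
`max_num_step` budget whose exhaustion is an error naming the setting.
Defaults are `rtol = atol = 1e-6`, `max_num_step = 100000`: at mg-scale
amounts and ANC-scale counts these put the integration error well below
residual error, and both tolerances should be moved together when the
negligible-scale of a state changes. Stiff/BDF methods are out of scope.

The coupled solver exploits the one-way structure of PK/PD systems: the
linear PK sub-state is advanced by its closed form and evaluated *at
every internal integrator time* (not held constant over an event
interval), while only the PD states are integrated numerically. This
keeps the "analytic PK" accuracy claim intact and shrinks the numerical
system from 8 to 5 states for the neutropenia model.

## Friberg–Karlsson myelosuppression model

A proliferating pool feeds three transit compartments and then the
circulating pool, all with transit rate `ktr = (n+1)/MTT`, `n = 3`. The
feedback `(Circ0/Circ)^γ` restores the baseline, and the drug scales the
proliferation rate by `1 − Edrug` with `Edrug = min(α·ĉ, 1)`; the cap
prevents the feedback loop from flipping sign at extreme concentrations
proposed during early MCMC exploration. `kprol = ktr` — required for the
baseline to be an equilibrium. States are kept as differences from
baseline so the initial condition is exactly zero; inside the dynamics
actual counts are floored at double machine epsilon (≈2.22e-16) and the
concentration at zero, so the right-hand side is finite for any state an
adaptive integrator may propose.

The drug-free return-to-baseline property is tested at 40·MTT: with the
weak canonical feedback (γ = 0.17) the slowest linearized mode has only
decayed to ~7e-5 of baseline by 20·MTT, so a shorter horizon tests the
integrator, not the model.

## Statistical model

Concentration and ANC streams are lognormal,
`y ~ LogNormal(log ŷ, σ)`, each stream with its own scale. The
population layer is `ϑ_j ~ LogNormal(log ϑ_pop, Ω)` with diagonal Ω
(log-scale standard deviations ω), and conventional allometric scaling
`(weight/70 kg)^0.75` for clearances and `(weight/70)^1` for volumes;
exponents and the reference weight are configurable, and the absorption
rate is never scaled.

Parameters are declared with bounds and priors; lower-bounded parameters
use a shifted-log transform, two-sided bounds a scaled logistic, and the
log-Jacobian enters the log joint density. Bounds may be expressions of
earlier parameters, evaluated per draw — the population absorption rate
is lower-bounded by the slower hybrid disposition rate
(`slow_disposition_rate`), which removes flip-flop non-identifiability.
The bound expression is a design choice: the constraint's intent is to
keep absorption the fastest identifiable process, and λ2 is the weakest
bound that does that.

A solver failure at a proposed parameter value maps to a log density of
−∞ (the sampler rejects) rather than an exception.

## Sampler

Adaptive HMC with a jittered path length replaces full trajectory-tree
building: warmup adapts the step size by Nesterov dual averaging toward a
0.8 target acceptance and a diagonal metric from windowed warmup draws
(15% initial buffer, doubling windows from 25 draws, 10% terminal
buffer, variance regularized toward unit scale); sampling runs with
frozen tuning. Each iteration integrates for a total time drawn
uniformly in [0.5, 1.5]× the configured path length (default 1.2,
capped at 64 leapfrog steps), which avoids the resonances of a fixed
length. A transition is divergent when the Hamiltonian *increases* by
more than 1000 (or turns non-finite) along the trajectory — the
criterion is one-sided on purpose: a large energy drop is a very good
proposal, and rejecting it would strand chains started in extreme tails.

Gradients are central finite differences with per-coordinate step
`cbrt(eps)·max(1, |x_i|)`, evaluated through a batched density so one
gradient costs a single vectorized sweep; an exact-gradient provider can
be plugged in. Finite differences keep the usable dimension modest —
population examples default to a handful of subjects.

Everything is deterministic given the seed (per-chain generators spawned
from one SeedSequence; data simulation uses counter-based Philox keys).

## Diagnostics, PPC, LOO

R-hat and ESS follow the rank-normalized split formulation: chains are
halved, draws replaced by normal scores of pooled fractional ranks, and
the reported R-hat is the larger of the bulk statistic and the statistic
on folded draws. Bulk ESS combines per-chain autocovariances with the
initial-positive-pair truncation and the monotone pair-sum correction;
tail ESS is the smaller ESS of the 5%/95% exceedance indicators. The
implementation matches an independent implementation of the same
published estimator (arviz) to near machine precision in the tests, and a
direct O(n²) brute-force re-implementation to 1%. Note the
rank-normalized R-hat *saturates* for gross failures (a chain shifted by
10 sd reads ≈1.5, not the >2 of the plain between/within formula); both
behaviours are asserted. ESS is reported uncapped — values above the
draw count on effectively independent chains are estimator noise, noted
rather than truncated. Summaries use type-7 quantiles and
1.4826-scaled MAD, and warn when any ESS drops below 100.

PSIS-LOO fits a generalized Pareto to the largest 20% of the importance
ratios per observation (minimum tail 5) by the Zhang–Stephens
profile-posterior method with their small-sample shape shrinkage,
replaces the tail by fitted quantiles truncated at the raw maximum, and
reports the tail index k̂ per observation with a warning above 0.7; a
tail too extreme to fit is flagged as k̂ = ∞ and left unsmoothed. Model
comparison sums pointwise elpd differences with
`se = sqrt(n·var(diff))`.

## Synthetic data: what it emulates, what it does not

The reference design reproduces the tutorial's single-subject study:
1200 mg oral boluses q12h × 14, dense sampling (0.083–8 h, 12 points)
after doses 1, 2 and 14, a predose sample before every dose, and 12/18/24
h follow-ups — 53 measurement rows, the last at 180 h. The time-zero
predose sample has model concentration exactly zero (nothing absorbed
yet), which a lognormal error cannot score; simulated datasets leave its
`dv` missing and likelihoods use the 52 rows with recorded values. The
structural 53-row design is preserved.

Default synthetic truth for examples and scripts is configuration, not a
code constant: CL 10 L/h, Q 15 L/h, Vcent 35 L, Vperi 105 L, ka 2 /h,
σ 0.2, and for the PD layer MTT 125 h, Circ0 5·10³ cells/µL, γ 0.17,
α 3e-3 per mg/L — canonical values from the population-PK and
myelosuppression literature. The generator draws lognormal residuals and
lognormal subject parameters with diagonal covariance; it does not
emulate BQL censoring, dropout, dose omissions, time-varying covariates,
correlated random effects, or model misspecification, so passing tests
certify the estimation machinery under the assumed model, not robustness
to real-data pathologies.

## Problem sizes used in tests and the acceptance script

Fits run 2 chains × 500 warmup/500 sampling draws on the 52-observation
design (the parameter-recovery check repeats this over 20 simulated
replicates), which yields bulk ESS of roughly 150–400 per parameter —
comfortably past the ESS ≈ 100 point where sampling error stops
mattering next to posterior spread. The model-comparison check fits the
two- and one-compartment models to the same simulated dataset and
compares PSIS-LOO; the exact-LOO cross-check uses a 10-observation
conjugate normal toy where every leave-one-out predictive is available
in closed form.

## Known limitations

* Finite-difference gradients scale linearly in dimension; large
  population fits want an exact-gradient provider (the hook exists).
* Only diagonal Ω; no Michaelis–Menten elimination or Emax drug effect.
* No stiff solver; the explicit RK4(5) pair assumes non-stiff dynamics
  at the fitted parameter scales.
* Steady state on arbitrary numeric right-hand sides is not implemented
  (it needs a root find over the period map); linear-model steady state
  is exact.
* Exact reproduction of the originally published posterior summary
  requires that study's released dataset (see `pmxbayes.reproduce`);
  without it the refit machinery is present but cannot be exercised.
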