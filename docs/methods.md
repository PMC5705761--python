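# Methods

## Model

The package simulates a one-dimensional inertial Brownian particle in a
spatially periodic potential with broken reflection symmetry, driven by an
unbiased time-periodic force and coupled to a thermal bath.  In dimensionless
form (lengths in units of the potential period over 2π, times in units of
τ̃₀ = ΓL²/ΔU, energies in units of the barrier height ΔU) the Langevin
equation is

    m ẍ + ẋ = −U′(x) + a cos(ω t) + √(2θ) ξ(t),

with ⟨ξ(t)⟩ = 0, ⟨ξ(t)ξ(s)⟩ = δ(t − s), and the 2π-periodic double-sine
ratchet potential

    U(x) = −[sin x + c · sin(2x + φ − π/2)],   c = 1/4.

The phase φ controls the asymmetry; φ = π/2 gives the canonical form
U(x) = −sin x − ¼ sin 2x, which is the default everywhere.  Breaking of the
mirror symmetry of U is necessary and sufficient for a nonzero directed
velocity under the unbiased drive; `Potential(asymmetry=0)` restores the
symmetric −sin x and is used as a null control in the tests.

The reference parameter set is m = 6, a = 1.899, ω = 0.403 with drive period
T = 2π/ω ≈ 15.59.  The dimensionless temperature θ = k_BT/ΔU measures
thermal energy against the barrier; the physically interesting window is
θ ~ 10⁻⁴–10⁻³.  `model.nondimensionalize` / `model.dimensionalize` convert
between dimensional parameters (M, Γ, L, ΔU, A, Ω, k_BT) and the
dimensionless groups, via m = M/(Γτ̃₀), a = (L/ΔU)A, ω = τ̃₀Ω, θ = k_BT/ΔU.
The four characteristic times τ̃₀ = ΓL²/ΔU, τ̃₁ = M/Γ, τ̃₂ = √(ML²/ΔU),
τ̃₃ = 2π/Ω satisfy τ̃₂² = τ̃₀τ̃₁ exactly and are exposed by
`characteristic_times`.

In a SQUID realization of the same equation the coordinate maps to the
Josephson phase, the velocity to the voltage drop, the mass to the loop
capacitance, the friction coefficient to the inverse resistance, the periodic
force to the external current, and φ to the applied magnetic flux.  Only this
naming correspondence is supported; no circuit-level modelling is attempted.

## Integrator

The engine advances (x, v) with a weak second-order stochastic
predictor–corrector (Heun) scheme for additive noise:

    predictor:  x* = x + dt·v
                v* = v + dt·f(x, v, t) + σ√dt·Z
    corrector:  x⁺ = x + dt·(v + v*)/2
                v⁺ = v + dt·[f(x, v, t) + f(x*, v*, t+dt)]/2 + σ√dt·Z

with drift f = [−U′(x) + a cos(ωt) − v]/m, noise amplitude σ√dt =
√(2θ·dt)/m, and the *same* Gaussian increment Z in both stages (required for
the weak-order result with additive noise).  The exact predictor–corrector
variant is a design choice; it is validated by its measured properties rather
than by matching any particular reference implementation:

* weak order 2 on the exactly solvable Ornstein–Uhlenbeck configuration
  (errors of ⟨v⟩ and ⟨v²⟩ fall ≈4× per halving of dt); because those errors
  are ~10⁻⁵ at the working step sizes, far below Monte-Carlo resolution, the
  test couples the scheme to the exact OU transition driven by identical
  Gaussians and measures the mean pathwise moment difference (a control
  variate that removes nearly all sampling noise);
* global order 2 on deterministic trajectories under dt-halving;
* equipartition ⟨v²⟩ = θ/m, the Einstein relation D → θ for the free
  particle, and the Boltzmann stationary density e^{−U/θ}/Z for the undriven
  ratchet (χ² test at 50 bins).

The integration step is dt = T/`steps_per_period`, so the drive period is an
integer multiple of dt by construction.  The default is T/1000; all
production-style runs in the tests and the reproduction script use T/200,
which the deterministic-convergence and weak-order checks show is well inside
the order-2 regime for these parameters (relative moment errors ~10⁻⁵).

Coordinates are integrated unwrapped (winding accumulates), because σ²ₓ(t)
requires unbounded x; `wrap_position` folds positions into [0, 2π) for
stationary-density tests only.

## Randomness

Each trajectory owns a counter-based Philox stream spawned from the master
seed via `SeedSequence.spawn`; a trajectory's initial condition and its whole
noise history come from its own stream.  Results are therefore bitwise
independent of ensemble batching: simulating trajectories [i:j] alone
reproduces rows [i:j] of the full ensemble.  Initial conditions default to
x(0) ~ U[0, 2π], v(0) ~ U[−2, 2].

## Observables

* σ²ₓ(t): unbiased (n−1) ensemble variance at each stroboscopic sample, with
  standard errors from the fourth central moment.  The (n−1) convention is a
  documented package-wide choice.
* D(t) = σ²ₓ(t)/2t, dropping the undefined t = 0 sample.  An increasing D
  means superdiffusion, decreasing subdiffusion, constant normal diffusion.
* v(t) = [x(t+T) − x(t)]/T on consecutive non-overlapping periods — an exact
  evaluation of the defining time-average of ẋ.  Its ensemble mean and
  variance are reported per window; the directed velocity ⟨v⟩ is the
  long-time mean, with its uncertainty computed across trajectories (windows
  within one trajectory are strongly correlated).
* α: least-squares slope of log σ²ₓ vs log t.  The default fit window is the
  last decade of data (the asymptotic part); both edges are configurable
  because published fits do not specify per-temperature windows.
* τ₁, τ₂: the diffusion-coefficient curve is interpolated onto a uniform
  log₁₀ t grid, smoothed by a Savitzky–Golay local quadratic of bandwidth
  0.25 decades, and differentiated.  τ₁ is the first downward zero crossing
  of the slope (the maximum of D, end of the superdiffusive stage); τ₂ is
  the first later time at which |slope| < ε = 0.05 holds over a full
  smoothing window.  Bandwidth and ε are config-exposed; crossings absent
  within the horizon leave validity flags unset rather than fabricating a
  value.  No extraction rule is published for these times; this segmentation
  reproduces the described shape of D(t) without manual inspection.

## Three-state coarse-graining

Window velocities are mapped to the bands [c − ν, c + ν) around the state
centers c ∈ {−0.4, 0, 0.4} with threshold ν = 0.2 (bands scanned in
ascending order; a value on a shared edge belongs to the band whose lower
endpoint it is; velocities outside all bands get an auxiliary `other` symbol
so the mapping is total).  Transition probabilities are relative frequencies
of (window k → window k+lag) pairs pooled over trajectories and over the
post-transient time range; lag defaults to one drive period — the simplest
Markov-chain reading — and the transient discard defaults to 10³ periods.
Rows are normalized over all four destinations, so every defined row sums
to 1 exactly; rows never visited stay undefined (NaN) rather than being
filled.  Occupation probabilities carry Wilson 95% intervals.

Deterministic attractors are identified by average-linkage agglomerative
clustering of per-trajectory late-time window velocities, cut at a merge
tolerance of 0.05 (half the band spacing).  Cluster diameters above the
tolerance raise a non-convergence warning (transient too short).  At the
reference parameters the θ = 0 dynamics is non-chaotic — the Benettin/QR
Lyapunov estimator returns non-positive largest exponents in every basin —
and three attractors coexist: two running states at ±ω/1 ≈ ±0.403 (one
spatial period per drive period) and a locked state at 0.

## Reference processes

`reference.generate_reference` produces fixtures with known statistics so
each analysis stage is testable without the ratchet simulation: ballistic
motion (σ²ₓ = Var(v₀)t², α = 2), free Brownian motion with exact Gaussian
increments (σ²ₓ = 2θt), the Ornstein–Uhlenbeck velocity process sampled with
its exact discrete transition (no integrator error; also the oracle for the
weak-order test), and deterministic piecewise-power mean-square-displacement
curves with prescribed exponents and break times (oracles for the α fit and
the crossover detector).  These emulate the *statistical* structure of the
ratchet's observables, not its dynamics; tests passing on them validate the
estimators, not the physical claims, which are exercised separately on the
simulator itself.

## Problem sizes

Ensembles and horizons are chosen so the full suite runs in minutes on one
core while keeping Monte-Carlo error well below the tested effects:
deterministic attractor scans use 500 initial conditions × 600 drive periods
(transient 500, averaging window 100); the crossover-time run uses 2048
trajectories to horizon 2·10⁴ (τ₁ ≈ 3·10³ sits comfortably inside); the
localization run uses 512 trajectories to horizon 5·10⁴ with the occupation
pooled over t ∈ [10⁴, 5·10⁴].  The asymptotic regime (horizons 10⁶–10⁸,
where the subdiffusive transient ends at τ₂ ≈ 10⁸) is reachable with the
same code via the `configs/asymptotic_*.yaml` runner configs, which are
overnight single-CPU jobs.

## Known limitations

* τ₂ at the reference temperature lies far beyond desk horizons; the
  detector reports it as invalid there (by design) and has been validated on
  synthetic curves instead.
* The transition-matrix estimator treats pooled windows as exchangeable;
  within-trajectory correlation means its counts are not independent, so the
  reported matrices are point estimates without confidence intervals.
* Survival probabilities depend on the chosen threshold ν; no published
  sensitivity table exists, so ν is exposed as configuration and only the
  default ν = 0.2 is exercised quantitatively.
* The weak-order guarantee is for expectations of smooth functionals;
  pathwise (strong) accuracy is not claimed.
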