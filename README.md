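# ratchetdl

Simulation and analysis of a driven inertial Brownian ratchet that exhibits
**transient subdiffusion caused by thermal-noise-induced dynamical
localization** of the period-averaged velocity.

The package is aimed at researchers in stochastic transport / molecular-motor
modelling who want a tested, reproducible pipeline for the full chain:
underdamped Langevin simulation → diffusion-anomaly diagnostics →
coarse-grained velocity-state kinetics.

## The model

A Brownian particle of dimensionless mass *m* moves in a 2π-periodic ratchet
potential under an unbiased time-periodic drive and thermal white noise:

    m ẍ + ẋ = −U′(x) + a cos(ωt) + √(2θ) ξ(t),
    U(x)    = −sin x − ¼ sin 2x,

with ⟨ξ(t)ξ(s)⟩ = δ(t−s) and θ = k_BT/ΔU the thermal energy in units of the
barrier.  At the reference parameters *m* = 6, *a* = 1.899, *ω* = 0.403 the
noise-free dynamics is non-chaotic and has three coexisting attractors of the
period-averaged velocity **v**(t) = [x(t+T) − x(t)]/T (T = 2π/ω): running
states v± ≈ ±0.4 and a locked state v₀ ≈ 0.

The diagnostics are the position variance σ²ₓ(t), the time-dependent
diffusion coefficient D(t) = σ²ₓ(t)/2t, the scaling index α of
σ²ₓ(t) ∼ t^α, the crossover times τ₁/τ₂ bounding the transient
super-/subdiffusive stages, and the three-state coarse-graining of **v**(t)
into bands |v ∓ 0.4| < ν and |v| < ν with threshold ν = 0.2, whose
occupation and transition probabilities expose the localization mechanism:
in a temperature window around θ ≈ 7·10⁻⁴ nearly all trajectories collapse
into the plus running state (p₊ ≈ 1), freezing the spread of positions.

## Worked example

```python
import numpy as np
from ratchetdl import (SimulationParams, simulate_ensemble, position_variance,
                       diffusion_coefficient, detect_crossovers,
                       period_averaged_velocity, coarse_grain,
                       occupation_probability, transition_probabilities, State)

params = SimulationParams(theta=7e-4, steps_per_period=200,
                          t_max=2e4, n_traj=256, seed=7)
rec = simulate_ensemble(params)

var = position_variance(rec)
fit = detect_crossovers(diffusion_coefficient(var))
print(f"tau1 = {fit.tau1:.3g} (valid={fit.tau1_valid}), "
      f"tau2 valid={fit.tau2_valid}")

pv = period_averaged_velocity(rec)
seq = coarse_grain(pv)
occ = occupation_probability(seq, State.PLUS, t_range=(1e4, 2e4))
tm = transition_probabilities(seq, t_range=(1e4, 2e4))
print(f"plus-band occupation = {occ.probability:.4f}")
print(f"p_++ = {tm.named()['p_++']:.4f}")
```

Output (≈10 s on one core):

```
tau1 = 3.05e+03 (valid=True), tau2 valid=False
plus-band occupation = 1.0000
p_++ = 1.0000
```

Read: superdiffusion ends at τ₁ ≈ 3·10³ (D(t) peaks there); the ensuing
subdiffusive stage extends beyond this horizon, so τ₂ is correctly flagged
as not yet reached; and during t ∈ [10⁴, 2·10⁴] the period-averaged velocity
is fully localized in the plus band — the mechanism behind the suppressed
spreading.

A command-line interface mirrors the library
(`ratchetdl simulate | deterministic-scan | analyze | states | sweep |
reference`, all accepting `--config`/`--seed`); YAML experiment configs live
in `configs/`, including overnight-scale runner configs
(`asymptotic_*.yaml`) for the t_f = 10⁶ horizons that desk-scale runs do not
reach.

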