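# Full-scale period-averaged-velocity variance at the final time t_f = 1e6,
# as a function of temperature (the localization signature: the variance is
# several times smaller inside the subdiffusive temperature window).
# Overnight run on one CPU.
physics:
  m: 6.0
  a: 1.899
  omega: 0.403
numerics:
  steps_per_period: 200
  t_max: 1.0e+6
  n_traj: 512
  seed: 2019
analysis:
  transient_periods: 1000
thetas: [1.6e-4, 4.0e-4, 7.0e-4, 8.5e-4, 1.175e-3, 2.0e-3]
output_dir: results/asymptotic_velocity_variance
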