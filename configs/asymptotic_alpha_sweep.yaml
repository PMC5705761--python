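# Full-scale scaling-index sweep: alpha(theta) fitted to the asymptotic part
# of sigma_x^2(t) at horizon t_f = 1e6.  Overnight run on one CPU
# (roughly 1-2 h per theta at this ensemble size); intended for the
# asymptotic claims that desk-scale runs cannot reach.
physics:
  m: 6.0
  a: 1.899
  omega: 0.403
numerics:
  steps_per_period: 200
  t_max: 1.0e+6
  n_traj: 1024
  seed: 2017
  sample_stride_periods: 4
analysis:
  alpha_window_decades: 1.0
  transient_periods: 1000
thetas: [1.0e-4, 1.6e-4, 3.0e-4, 5.0e-4, 7.0e-4, 8.5e-4, 1.0e-3, 1.175e-3,
         1.5e-3, 2.0e-3]
output_dir: results/asymptotic_alpha_sweep
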