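# Full-scale three-state transition-probability sweep at horizon 1e6:
# survival probabilities p_++, p_00, p_-- and the localization window as a
# function of temperature.  Overnight run on one CPU.
physics:
  m: 6.0
  a: 1.899
  omega: 0.403
numerics:
  steps_per_period: 200
  t_max: 1.0e+6
  n_traj: 512
  seed: 2018
  sample_stride_periods: 1
analysis:
  threshold_nu: 0.2
  state_centers: [-0.4, 0.0, 0.4]
  lag_periods: 1
  transient_periods: 1000
thetas: [1.0e-4, 2.0e-4, 4.0e-4, 7.0e-4, 1.175e-3, 2.0e-3, 5.0e-3, 1.0e-2]
output_dir: results/asymptotic_transition_sweep
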