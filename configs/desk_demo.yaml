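# Desk-scale demonstration sweep (~2 min on one CPU core).
# Three noise intensities bracketing the subdiffusive window; short horizon,
# so the anomaly diagnostics show the transient (not asymptotic) behaviour.
physics:
  m: 6.0
  a: 1.899
  omega: 0.403
  phi: 1.5707963267948966   # pi/2: canonical ratchet  -sin x - (1/4) sin 2x
numerics:
  steps_per_period: 200
  t_max: 1.0e+4
  n_traj: 256
  seed: 12345
analysis:
  threshold_nu: 0.2
  state_centers: [-0.4, 0.0, 0.4]
  transient_periods: 200
thetas: [1.6e-4, 7.0e-4, 1.175e-3]
output_dir: results/desk_demo
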