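# Worked two-early-look design: small trial, sigma3 = 18,
# rho13 = rho23 = 0.5, rho12 = 0.
alpha: 0.025
spending:
  lower: [0.200, 0.600, 0.975]
  upper: [0.000, 0.001, 0.025]
looks:
  counts_per_arm: [[20, 15, 10], [25, 20, 15]]
final_n_per_arm: 30
assumed_model:
  sigma: 18
  rho: [0.0, 0.5, 0.5]
policy:
  binding: true
  monitor_start_month: 0
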