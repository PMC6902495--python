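# Two-early-look full-size design under a 10-point treatment difference.
design:
  alpha: 0.025
  spending:
    lower: [0.24, 0.72, 0.975]
    upper: [0.0, 0.001, 0.025]
  looks:
    counts_per_arm: [[55, 40, 20], [70, 55, 35]]
  final_n_per_arm: 85
  assumed_model:
    sigma: 20
    rho: 0.5
  recruitment:
    centres: [1, 2, 3, 6, 9, 12, 15]
    rate: 0.5611
    cap: 170
  policy:
    binding: true
    monitor_start_month: 18
truth:
  sigma: 20
  rho: 0.5
  delta: 10
reps: 1000
seed: 1
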