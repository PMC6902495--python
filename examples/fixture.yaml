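# Synthetic interim dataset emulating the worked example's first look.
model:
  sigma: 18
  rho: [0.0, 0.5, 0.5]
  delta: -10
counts_per_arm: [[20, 15, 10], [20, 15, 10]]
reference_time: 18.0
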