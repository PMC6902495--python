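# augseq

Design, monitoring and simulation of two-arm group-sequential clinical
trials in which early (short-term) measurements of the primary outcome
augment the long-term endpoint at interim analyses.

The package provides:

- **`augseq.effect`** — the augmented treatment-effect estimator `B`, its
  variance and information content, nuisance-parameter estimation (pooled
  moments or sequential-regression factorization), and fixed-design sample
  size. With two early endpoints the variance has the closed form
  `var(B) = (2σ²/N₃)[1 − ρ₁₃²(N₁−N₃)/N₁ − ρ₂₃²(N₂−N₃)/N₂ + 2ρ₁₃ρ₂₃ρ₁₂(1−N₃/N₂)]`;
  a general-K extension is derived by exact covariance algebra.
- **`augseq.boundaries`** — error-spending futility/efficacy boundaries on
  the canonical joint distribution of sequential z-statistics, via a
  stagewise numerical-integration recursion (binding or non-binding), plus
  crossing-probability evaluation under arbitrary drift.
- **`augseq.engine`** — interim decision making on a dataset: event-driven
  information monitoring, look triggering when observed information reaches
  its planned level, boundary comparison (stop for futility iff `S < l`,
  efficacy iff `S ≥ u`), and the overrunning (definitive) analysis.
- **`augseq.simulate`** — virtual trials end to end: staged multicentre
  Poisson recruitment, permuted-block allocation, multivariate-normal
  outcomes, sequential monitoring and decisions, and operating
  characteristics (stopping probabilities, power, type I error, expected
  sample size) over replicates.
- **`augseq.io` / `augseq.cli`** — CSV datasets, YAML/JSON design and
  scenario configs (strictly validated), JSON reports, and a synthetic
  interim-dataset fixture generator.

## Command line

```bash
# stopping boundaries for a design config
augseq boundaries --design examples/design.yaml --out bounds.json

# operating characteristics for a scenario
augseq simulate --scenario examples/scenario.yaml --reps 1000 --seed 1 --out oc.json

# interim analysis of a dataset at one look
augseq analyze --data trial.csv --design examples/design.yaml --look 1 --out decision.json

# synthetic interim fixture
augseq generate-data --config examples/fixture.yaml --seed 7 --out trial.csv
```

Exit code 2 signals a validation error (unknown config keys, malformed
rows, infeasible spending).  A design config looks like:

```yaml
alpha: 0.025
spending:
  lower: [0.200, 0.600, 0.975]   # cumulative futility spending
  upper: [0.000, 0.001, 0.025]   # cumulative efficacy spending
looks:
  counts_per_arm: [[20, 15, 10], [25, 20, 15]]   # (N1, N2, N3) per early look
final_n_per_arm: 30
assumed_model:
  sigma: 18
  rho: [0.0, 0.5, 0.5]           # rho12, rho13, rho23
policy:
  binding: true
  monitor_start_month: 18
```

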