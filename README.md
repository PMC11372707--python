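# forcefluct

Analysis pipeline for the magnitude and structure of force fluctuations in
bimanual force-control tasks. The package provides:

- **`forcefluct.synthetic`** — benchmark noise generators (white, Brownian,
  tunable power-law), single bimanual-trial simulation (constant target vs
  sine-wave target with optional crosstalk leakage), a cognitive-screening
  classifier (MoCA < 26 plus at least one CERAD-NP domain z-score below
  −1.5 → MCI), and cohort-sequential dataset generation with a configurable
  measure-scale generative model (fixed effects + participant random
  intercepts).
- **`forcefluct.preprocessing`** — ramp-phase exclusion, normalization to
  percent of maximum voluntary contraction, z-scaling, and per-cell
  aggregation of trial-level measures.
- **`forcefluct.measures`** — coefficient of variation (100·SD/mean, sample
  SD), detrended fluctuation analysis (integrate, non-overlapping linear
  detrending windows, mean per-window RMS, log–log slope over 30
  exponentially spaced window sizes from 10 to 200), and sample entropy
  (m = 2, r = 0.25 on the z-scaled series, Euclidean distance by default with
  Chebyshev available), plus the m × r robustness grid.
- **`forcefluct.inference`** — linear mixed models with participant random
  intercepts, a stepwise model sequence (main effects, all 2-way
  interactions, selected higher-order terms) with AIC selection and
  likelihood-ratio tests, containment-style denominator degrees of freedom,
  and contrast tables with effect sizes r = √(t²/(t²+df)).
- **`forcefluct.pipeline` / `forcefluct.cli`** — orchestration of
  simulate → measure → infer with CSV/JSON artifacts, reproducibility
  headers (seed + config hash) and a run manifest.

## CLI

```sh
# end-to-end on a small synthetic cohort described by a YAML config
forcefluct all --config examples.yaml --out-dir out --seed 1

# individual stages
forcefluct simulate --out-dir out --seed 1
forcefluct measure  --trials-csv out/trials.csv --out-dir out
forcefluct infer    --measures-csv out/measures.csv --out-dir out

# small bundled test inputs with precomputed oracle outputs
forcefluct fixtures --out-dir fixtures
```

A config file mirrors `PipelineConfig` (see `forcefluct/pipeline.py`), e.g.:

```yaml
ramp_s: 6.0
cohort:
  counts: {CHI: [6, 3, 0, 0], MCI: [4, 2, 0, 0]}
  trials_per_cell_constant: 2
  trials_per_cell_rd: 8
  trial: {duration_s: 20.0, ramp_s: 6.0, rate_hz: 120.0}
```

Exit codes: 0 success, 2 config error, 3 stage failure. Every output CSV
opens with `#` header lines recording the package version, the run seed and
a hash of the effective configuration; rerunning with the same values
reproduces the file byte for byte.

Note that the default cohort structure (77/52/33/11 vs 55/34/15/3 subjects
over four timepoints, 2 + 8 + 8 trials of 20 s at 120 Hz per cell) produces
a large trials CSV when simulated at signal level; use reduced counts or
shorter trials for quick runs.

## Layout

```
src/forcefluct/     package modules
tests/              pytest suite (unit, property, acceptance criteria);
                    tests/oracles.py holds independent brute-force
                    reference implementations of DFA and sample entropy
scripts/acceptance.py   acceptance report generator
```
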