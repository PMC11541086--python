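# oscana

Oscillation analysis for paired-region electrophysiology, with a fully
synthetic, seed-deterministic test bed. The package implements:

- **`oscana.synthgen`** — generators for coupled theta/gamma region
  pairs (tunable coupling depth, inter-region coherence, noise),
  switching-topography EEG with ground-truth state labels, stimulus-
  locked evoked epochs, and two-group score samples with optional exact
  moment matching.
- **`oscana.spectral`** — segment-averaged auto/cross spectra
  (boxcar/Hann/multitaper), magnitude-squared coherence with the
  analytic confidence limit `1 − (1−α)^(1/(M−1))`, Morlet-wavelet power
  (3-cycle wavelets, magnitude or squared magnitude), band summaries,
  and integrated band power. Band profiles (human theta 4–8 Hz vs mouse
  theta 7–12 Hz, gamma 30–100 Hz with a 70 Hz low/high split) are
  explicit — profile selection is mandatory wherever bands are implied.
- **`oscana.pac`** — phase-amplitude coupling with the binned
  modulation index `m = (max(p) − min(p))/max(p)` in both the
  narrowband-phase and band-envelope variants, comodulograms, and a
  circular-shift surrogate null. On a noiseless envelope
  `a(1 + d·cos φ)` the index recovers `2d/(1+d)`.
- **`oscana.microstates`** — GFP, GFP-peak picking, polarity-invariant
  modified k-means into k=4 prototype classes, back-fitting, and
  per-class duration / occurrence / coverage statistics.
- **`oscana.evoked`** — global mean field power of stimulus-locked
  evoked responses over an electrode subset (RMS deviation from the
  subset mean), band power over intervals, and baseline-normalized
  condition ratios.
- **`oscana.bayescompare`** — MCMC two-group comparison (Gibbs;
  Gaussian likelihood by default, robust Student-t optional) reporting
  the directional probability-of-difference, the posterior effect-size
  mode for `(µ1−µ2)/√((σ1²+σ2²)/2)`, and 80%/90% significance tiers;
  plus a JZS-family Bayes-factor one-way ANOVA with 3/10/100 verdict
  thresholds, and a tidy-table driver with optional covariate
  residualization.
- **`oscana.pipeline`** — two-cohort synthetic studies from a single
  YAML/JSON config: generate → analyze → compare → report, with config
  hash and seed embedded in every output and byte-identical re-runs.

## CLI

All commands are subcommands of `oscana` (see `--help` on each):

```bash
# generate a coupled pair, then analyze it
oscana synth --kind coupled --out data/ --seed 1 --coupling-depth 0.5
oscana coherence --x data/region_A.tsv --y data/region_B.tsv -L 1024 --out coh.csv
oscana pac --phase-region data/region_A.tsv --amp-region data/region_B.tsv \
    --profile mouse --out pac.json

# microstates and group statistics
oscana synth --kind microstates --out data/ --duration 30 --fs 250
oscana microstates --eeg data/eeg.tsv --k 4 --restarts 100 --seed 1 --out ms/
oscana compare --table scores.csv --draws 100000 --seed 1 --out cmp.csv

# a full two-cohort study from a config file
oscana study --config study.yaml --out study_out/ --seed 1
```

A minimal study config:

```yaml
profile: mouse        # mandatory: 'human' or 'mouse' (band definitions differ)
n_subjects: 8
cohorts:
  control: {}
  carrier: {coherence_mix: 0.2, gamma_coherence_mix: 0.8}
```

Recordings are exchanged as delimited text matrices (one row per
channel) with a `.json` sidecar carrying `fs`, channel labels, and
units.

## Notes

- Every generator and sampler takes an explicit seed; identical seeds
  give identical outputs (MCMC included).
- `tests/test_acceptance.py` runs the acceptance criteria at reduced
  MCMC draw counts (50k) to stay inside CI budgets; tolerances are
  unchanged.
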