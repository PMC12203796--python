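# v1phys

Analysis toolkit for visual-cortex physiology experiments comparing two
mouse genotypes (wild-type vs a channelopathy model):

* **`v1phys.ephys_features`** — passive-membrane and action-potential
  feature extraction from current-clamp step protocols (threshold by the
  15.2 mV/ms dV/dt rule, half-width with sub-sample interpolation,
  rise/fall times and maximal rates, R_in / τ / capacitance, sag,
  rebound, rheobase).
* **`v1phys.csf_pipeline`** — two-photon ΔF/F traces + stimulus epochs →
  per-cell ordinal contrast-sensitivity categories
  (log2(1/minimum responsive contrast), "NR" when nonresponsive),
  population CSFs (mean + IQR over non-NR cells) and responding
  proportions.
* **`v1phys.ordinal_model`** — cumulative link mixed model (per-animal
  random intercept, adaptive Gauss–Hermite quadrature, logit/probit
  links), analysis of deviance, Cox–Snell pseudo-R², and per-SF marginal
  genotype contrasts with Benjamini–Hochberg correction.
* **`v1phys.group_stats`** — Shapiro-gated two-sample comparisons
  (Welch t / rank tests), Bonferroni and Benjamini–Hochberg corrections,
  Wilson's test of equal proportions, PV⁺-density ANOVA.
* **`v1phys.synthetic_data`** — generators with closed-form ground truth:
  current-clamp sweeps with piecewise-analytic AP templates, calcium
  datasets from log-Gaussian SF tuning × Naka–Rushton contrast response
  convolved with an indicator kernel, and per-section Poisson cell
  counts. Every downstream stage is testable without any external data.
* **`v1phys.cli_io` / `v1phys.cli`** — neutral exchange formats (HDF5
  sweep containers, tidy CSV tables, YAML/TOML run configs), run
  manifests with checksums, and a subcommand CLI.

## CLI

```sh
v1phys simulate-ephys  --seed 7 --out runs/ephys
v1phys extract-ap      --sweeps runs/ephys/sweeps.h5 --out runs/features
v1phys simulate-imaging --seed 7 --out runs/imaging
v1phys csf             --data-dir runs/imaging --out runs/csf
v1phys clmm            --cs-table runs/csf/cs_table.csv --out runs/clmm
v1phys pv-density      --seed 7 --out runs/pv
v1phys stats           --table runs/features/features.csv --out runs/stats
v1phys report          --run-dir runs --out runs/report
```

Every command writes a `manifest.json` (tool version, resolved-config
hash, seed, input checksums, output list); deterministic stages are
bit-reproducible under a fixed seed. Stage knobs (responsiveness
thresholds, CLMM link/quadrature, simulator parameters) live in a
YAML/TOML config passed via `--config`; unknown keys are rejected.

## Conventions

Time in ms and voltage in mV in the ephys layer (maximal rates reported
in mV/s in feature tables); frames are 0-based with half-open
`[onset, offset)` windows; AP amplitude is threshold-to-peak; CSV output
is UTF-8 with '.' decimals.
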