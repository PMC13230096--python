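# spotmap

Small-area disease-risk mapping in Python: age-standardized expected
counts per areal unit, a negative binomial BYM2 hierarchical spatial
Bayesian model producing unit-level relative risks (RRs),
credible-interval hot/cold-spot classification, and rurality- and
deprivation-stratified nonparametric comparisons. A synthetic-data
module generates lattice geographies with known truth so the whole
pipeline can be exercised end to end without restricted registry data.

## Components

| module                    | role |
|---------------------------|------|
| `spotmap.geography`       | contiguity graphs (queen/rook) from polygon layers or GAL files, connected components, ICAR scaling factors |
| `spotmap.standardization` | age-banded expected counts (internal or standard-weighted), zero-population / zero-case exclusions |
| `spotmap.model`           | NB-BYM2 joint density, in-package NUTS sampler, convergence diagnostics |
| `spotmap.classify`        | RR posterior summaries, equal-tailed CrIs, hot/cold/ns labels, GeoJSON/PNG map export |
| `spotmap.stratify`        | RUCA recoding, ADI quartiles, Kruskal–Wallis, Dunn's tests with Holm adjustment, median-difference reports |
| `spotmap.synth`           | synthetic lattices: populations, covariates, BYM2 fields, planted hot blocks |
| `spotmap.cli`             | the `spotmap` command: stage orchestration, config, manifests |

The model is
`O_i ~ NegBin(mu_i, psi)` with `Var = mu + mu^2/psi`,
`log mu_i = log E_i + beta0 + b_i`, and
`b_i = (1/sqrt(tau)) (sqrt(1-phi) v_i + sqrt(phi) u_i / sqrt(c))`,
where `u` is an ICAR field scaled per connected component by the factor
`c` (geometric mean of the ICAR marginal variances) and `v` is iid
normal. Units with no neighbors receive the unstructured term only.
Sampling is done by an in-package No-U-Turn sampler with dual-averaging
step size and diagonal mass adaptation; fits are bit-reproducible given
a seed.

## CLI quick start

```sh
# synthetic dataset + full pipeline in one run directory
spotmap synth --out runs/demo --seed 7 --rows 15 --cols 15
spotmap standardize --out runs/demo
spotmap fit --out runs/demo
spotmap classify --out runs/demo
spotmap stratify --out runs/demo
spotmap report --out runs/demo
```

or with a config file (`spotmap run --config run.yaml --with-synth`):

```yaml
output_dir: runs/demo
seed: 7
contiguity: queen            # or rook
standardization_mode: internal
levels: [0.95, 0.99]
reference_ruca: metropolitan
reference_adi: Q1
sampler: {chains: 4, draws: 1000, warmup: 1000, target_accept: 0.9}
priors:  {beta0_sd: 10.0}
synth:   {rows: 15, cols: 15, target_mean_e: 40.0, phi: 0.7, tau: 4.0, psi: 10.0}
```

Real data enters through `area_csv` (columns `unit_id, cancer_type, O,
pop_band_1..pop_band_11, ruca, adi`, optionally `obs_band_*`), plus
either a GeoJSON polygon layer (`geojson`, id property configurable via
`id_field`) or a GAL adjacency file (`gal`). A standard-population
weight table (`band, weight`) is used in `standard_weighted` mode.

Each run directory contains the persisted config, exclusion log,
expected counts, posterior draws (CSV), convergence diagnostics, risk
summaries and spot labels per credible level, GeoJSON/PNG maps,
stratified reports, and a `manifest.json` with SHA-256 checksums of
every artifact. Reruns with the same seed reproduce the manifest
exactly.

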