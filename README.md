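# glvnet

Signed, directed microbial interaction networks from replicate time-series
abundance data.

Given a genus-level count table sampled over time in replicate animals (two
groups, e.g. a control and a treatment cohort), `glvnet`:

1. fits a discrete generalized Lotka–Volterra (gLV) regression to every
   *replicate assembly* — a composite time series built by choosing one
   replicate's sample at each time point (R replicates × K time points →
   R^K assemblies, enumerable in full or subsampled);
2. keeps an interaction *j → i* only if its fitted coefficient carries the
   same sign in strictly more than a consensus cutoff (default 70%) of the
   ensemble members — the sign-consensus **reliable interaction network**;
3. ranks taxa by degree, betweenness, and closeness centrality, sums the
   three component ranks, and dense-ranks the total: taxa at final rank 1
   are the **key microbes** (validated by an OLS rank regression);
4. classifies community members as high/low/rare abundance (mean relative
   abundance >1%, [0.1%, 1%], <0.1%) and core/non-core (present in all
   samples of the evaluated scope), and computes alpha diversity
   (coverage-adjusted nonparametric Shannon, inverse Simpson, Chao1) with a
   permutation two-sample t-test;
5. compares groups' cooperation/competition balance: per-member proportions
   of positive vs negative fitted interactions, Shapiro–Wilk normality
   checks, and a Wilcoxon rank-sum comparison with direction.

A synthetic-community module generates ground-truth gLV dynamics (stable,
equilibrium-anchored random interaction matrices), replicate trajectories,
and multinomial sequencing-style counts, so the entire pipeline is testable
without external data.

## Command-line interface

Every stage is independently invocable; `run` executes the whole pipeline:

```bash
glvnet run --config config.yaml [--seed 1] [--outdir out] [--full-ensemble] [--focal Lactobacillus]
glvnet validate --config config.yaml
glvnet simulate --outdir sim --seed 1
glvnet classify  --shared sim/abundance.shared.tsv --metadata sim/abundance.metadata.tsv --out membership.csv
glvnet diversity --shared ... --metadata ... --out diversity.csv
glvnet infer     --shared ... --metadata ... --group sham --outdir out
glvnet topology  --edges out/network_sham.edges.csv --out centrality.csv --focal Oscillospira
glvnet stability --profile-a out/stability_sham.csv --profile-b out/stability_sni.csv --out comparison.json
```

### YAML configuration

Exactly one of `input` (paths to a mothur-style `shared` TSV plus a
sample→group/replicate/day metadata TSV) or `synthetic` (a design block)
must be present. Unknown keys are errors. Defaults shown:

```yaml
input: null              # {shared: path, metadata: path}
synthetic:               # or a synthetic-study design
  n_taxa: 20
  replicates_per_group: 3
  time_grid: [-1, 0, 1, 1.4, 2, 3, 4, 5, 6, 7, 14]
  library_size: 10000
  noise_sd: 0.05
  density: 0.15
  strength_scale: 1.0
  positive_fractions: [0.5, 0.5]
  group_labels: [group1, group2]
groups: null             # analyze all groups in the table
ensemble:
  mode: subsample        # "full" enumerates all R^K (ceiling-gated)
  n_subsample: 2000
  ceiling: 200000
consensus_cutoff: 0.7
regression:
  backend: pls           # pls | ridge | ols
  n_components: 2
  ridge_lambda: 1.0
  pseudocount: null      # default: half the smallest nonzero value
membership:
  high_cutoff: 0.01
  rare_cutoff: 0.001
  scope: per_group       # or all_samples
focal_taxa: []
outdir: glvnet_out
seed: 0
```

Outputs per run: shared/metadata TSVs, membership CSV, diversity CSVs,
per-group edge-list CSV + GraphML + GEXF (Gephi-ready), centrality-rank
CSV, focal-interaction tables, per-member stability CSVs, a comparison
JSON, and a `manifest.json` listing every artifact with its SHA-256
checksum and the effective configuration — identical (config, seed) runs
are byte-reproducible.

## Notes on method choices

- The simulator and the estimator share one discretization
  (log-space Euler: `ln x(t+1) − ln x(t) = Δt (b + A x(t)) + ε`), so
  noiseless recovery tests are exact: with OLS and at least
  `n_taxa + 1` transitions the fitted coefficients match the generating
  parameters to machine-level tolerance.
- Partial least squares is the default regression backend because a
  desk-scale series (10 transitions) cannot identify 59+1 coefficients by
  OLS; `ridge` and `ols` are available for recovery tests and robustness.
- The `> 70%` consensus cutoff is a strict inequality on the member count
  (e.g. 124,003 of 177,147).
- Centralities are computed on the unweighted directed graph; a weighted
  variant (distance `1/|mean strength|`) is available but off by default.
- Sign recovery against ground truth is validated on absolute trajectories:
  per-sample normalization (closure) makes the gLV regression on relative
  abundances misspecified, which provably scrambles interaction signs —
  see the recovery tests for details.
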