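# Methods

## The question the package answers

Differential-expression (DE) testing on case/control single-cell RNA-seq data
must respect that cells are not independent: cells from the same donor share
a donor-level expression shift, so treating cells as replicates
("pseudoreplication") inflates the effective sample size and the type-1
error. The package simulates hierarchical counts with known DE, runs a roster
of testing strategies on the *identical* matrix, and scores them with
balanced measures — the Matthews correlation coefficient (MCC), type-1 error
at a fixed p-value cutoff, and ROC sensitivity at matched test size — so that
a method cannot look good by being merely conservative or merely liberal.

## Generative model

Genes are simulated independently, one substream each. For gene *g* with
baseline mean μ_g and fold change f_g:

1. **Baseline:** μ_g ~ LogNormal(`grand_mean_log_mu`, `grand_mean_log_sd`)
   (natural-log scale).
2. **Donor effect:** individual *i* draws δ_i ~ N(0, `sigma_ind`²) and has
   mean m_i = μ_g·exp(δ_i), multiplied by f_g iff *i* is a case. This shared
   δ_i is what correlates cells within a donor.
3. **Cell counts:** each of the donor's cells draws a latent count from a
   negative binomial with mean m_i and dispersion φ = `nb_dispersion`
   (Var = m + φ·m²), realized as a gamma–Poisson mixture; φ = 0 collapses to
   Poisson.
4. **Dropout:** the observed count is zeroed with probability
   σ(`dropout_intercept` − `dropout_slope`·log m_i), so lowly expressed
   genes drop out more, on top of the NB's own zeros.

DE genes are the first round(`n_genes`·`prop_de`) indices of a seeded
permutation — the DE count is exact, which keeps confusion-matrix
denominators deterministic. Fold-change magnitudes are uniform on
[`fc_min`, `fc_max`] on the natural scale (a log-uniform option exists via
`fc_log_uniform`), with direction up or down with probability ½ each so that
two-sided tests are not favoured.

### Default parameters

| parameter | default | why |
|---|---|---|
| `n_genes` | 10,000 | a filtered droplet gene panel |
| `prop_de` | 0.1 | mid-range of the studied DEG proportions (0.05–0.3) |
| `n_cases`, `n_controls` | 20 each | the cohort size of the headline ROC design |
| cells per individual | 100 | mid-range droplet yield per donor after QC |
| `fc_min`, `fc_max` | 1.1, 10 | biologically plausible DE span, from subtle to strong |
| `grand_mean_log_mu` | ln 2 | median ~2 counts/cell: moderately expressed genes |
| `grand_mean_log_sd` | 1.0 | ~e²-fold spread of baselines across genes |
| `sigma_ind` | 0.3 | ≈1.35-fold typical donor-to-donor shift, a realistic intra-donor correlation for cohort scRNA-seq |
| `nb_dispersion` | 0.5 | gene-level overdispersion typical of droplet counts |
| `dropout_intercept`, `dropout_slope` | −1.0, 0.5 | ~20% dropout at mean 2, ~40% at mean 0.3, <10% at mean 20 |

These defaults are the package's surrogate for the empirical fits of
donor-hierarchy simulators trained on real data; they are chosen once to
reproduce the qualitative structure that matters (intra-donor dependence and
zero inflation at realistic magnitudes), not to match any particular tissue.

### Seeding contract

A single `master_seed` spawns named `numpy` `SeedSequence` substreams keyed
by (purpose, gene index): gene baselines, the DE permutation, fold changes,
and one stream per gene's counts. Consequences, all asserted by tests:

* identical parameters + seed ⇒ bit-identical datasets;
* changing `prop_de` leaves the counts of genes whose DE status is unchanged
  bit-identical (stream isolation), and the smaller DE set is a prefix of
  the larger;
* every DE method within an iteration consumes the same matrix — each result
  carries a SHA-256 checksum of the counts so a benchmark run can prove it.

Fold-change draws are consumed pairwise (magnitude, direction) per gene so
the first *k* draws do not depend on how many are requested.

## DE methods

All continuous modelling uses log2(count + 1) (pseudocount 1); the hurdle's
positive part uses log2(count) on detected cells.

* **Pseudobulk: Mean / Sum** — aggregate to genes × individuals (mean divides
  by each individual's own cell count), then a per-gene Welch two-sample
  t-test on log2(value + 1) across individuals. A deliberately plain,
  deterministic sample-level engine: the benchmark's claims concern the
  *aggregation level*, not a particular count model. Optional
  counts-per-million scaling per individual (`normalize_cpm`) is off by
  default; note that because an individual's sum column is a scalar multiple
  of its mean column, CPM makes the two aggregations exactly identical.
* **Modified t** — the same Welch test with cells as units, ignoring donors:
  the canonical pseudoreplication baseline.
* **Tobit** — per-gene maximum-likelihood Gaussian regression of
  log2(count + 1) on group, left-censored at 0, cells as units; Wald test on
  the group coefficient. Fitted by BFGS on the analytic gradient with an OLS
  warm start; the observed information comes from central differences of
  that gradient. With no zeros the fit reduces to OLS (tested to 1e-6);
  all-zero genes have a degenerate likelihood and are reported as failures.
* **Two-part hurdle (Default / Corrected)** — per gene, a logistic regression
  of detection (count > 0) on group plus a linear regression of log2(count)
  on group among detected cells; the combined statistic is the sum of the two
  likelihood-ratio χ² referred to χ² with the summed degrees of freedom. A
  degenerate part (detection does not vary; too few detected cells to
  identify the group effect) contributes 0 df, so an all-detected gene is
  judged by the positive part alone. "Corrected" adds each cell's detection
  rate (fraction of genes detected in that cell) as a covariate in both
  parts. Both fits are batched across genes (shared design matrix, IRLS /
  weighted least squares via einsum normal equations); linear predictors are
  clipped at ±30 so separable genes converge to a finite near-zero deviance.
* **GEE1** — Gaussian generalized estimating equations (statsmodels) of
  log2(count + 1) on group, exchangeable working correlation, clusters =
  individuals, robust sandwich errors. With clusters of size one this equals
  heteroskedasticity-robust OLS (tested). Perfectly symmetric inputs
  collapse the sandwich variance to rounding error; a vanishing robust SE
  with a vanishing coefficient is reported as p = 1 ("no evidence") rather
  than a 0/0 artifact.

Missing p-values (failed fits, never-detected genes) are excluded from
confusion counts and reported, never imputed. Zero-variance equal-mean genes
get p = 1: "no evidence" is the correct verdict and keeps null calibration
conservative.

## Scoring conventions

* Positive call ⇔ p ≤ α, boundary **inclusive** (matters for tie-heavy
  discrete tests); default α = 0.05, unadjusted.
* MCC = (tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn)); any zero marginal
  gives 0. Cross-checked against scikit-learn's implementation.
* ROC curves sweep the unique p-values (ties form one point, no intra-tie
  interpolation), anchored at (0,0) and (1,1); AUC by trapezoid. AUC is
  invariant under strictly monotone transforms of p (tested).
* Sensitivity at a target FPR interpolates TPR linearly between bracketing
  curve points; vertical segments contribute their highest attained TPR.

## Benchmark design

`run_grid` crosses per-group individuals {5, 10, 20, 30, 40} with cells per
individual {50, 100, 250, 500} (configurable), `runs_per_cell` repeats each,
and derives each iteration's seed from the master seed and the design point —
so the table is identical under any execution order. The ROC study pools
p-values across runs *before* building each curve (pooling, not
curve-averaging, is the reproducible reading of a multi-run ROC), by default
at 20+20 individuals × 100 cells over DEG proportions {0.05, 0.1, 0.2, 0.3}.
The imbalanced study fixes unequal cells per individual between groups
(e.g. 150 vs 50) and reduces exactly to a grid point when equal.

## What the tests show — and what they cannot

The simulator reproduces the two features the method comparison hinges on:
donor-induced intra-class correlation and zero inflation. It deliberately
omits library-size variation across cells (each gene is simulated
independently, so there is no per-cell depth to normalize — the reason the
CPM step is off by default), gene–gene correlation, batch effects, and
empirically fitted parameter distributions. Passing benchmarks therefore
support the *relative* behaviour of testing strategies under donor
clustering; they do not certify absolute error rates on real tissue, where
donor effects are heavier-tailed and genes are correlated.

Observed behaviour at the defaults (all computed by the test suite or the
acceptance script, never hard-coded): pseudobulk mean holds type-1 error at
or just below 0.05 and reads >0.9 sensitivity off the pooled ROC at FPR 0.05;
the cell-level tests inflate type-1 error several-fold, worsening as cells
per donor grow; GEE1 sits near nominal but pays a small-cluster price; sum
aggregation collapses under cell-number imbalance unless CPM-normalized, and
after CPM the two aggregations coincide exactly. CPM under many strongly DE
genes also leaks signal into null genes (a compositional effect visible in
`examples/04_imbalanced_cells.py`).

## Problem sizes

Desk-scale defaults keep every study a few minutes on one CPU: the shipped
tests and the acceptance script use 300–1,000 genes, 10–20 individuals per
group, 50–500 cells per individual and 2–20 runs per condition, with
Monte-Carlo tolerances (3-binomial-σ bands, paired orderings) sized to those
runs. The full factorial (10,000 genes × 50 runs × the complete grid) is a
configuration choice away (`--scale full` in the CLI), not a different code
path.

## Known limitations

* The Tobit and hurdle implementations target the two-group (plus detection
  rate) design used here; they are not general regression engines.
* Gaussian GEE on log counts is a working-model choice; a count-family GEE
  would differ in small samples.
* The Welch-on-log2 pseudobulk engine is not a negative-binomial GLM; with
  very few individuals per group its t-approximation is rough (the benchmark
  grid starts at 5 per group for this reason).
* `simulate_dataset` materializes a dense genes × cells matrix; at the full
  10,000 × 20,000 scale this is ~0.8 GB of int32.
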