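"""Differential-expression testing strategies benchmarked on a shared dataset.

Three families, all consuming the same genes x cells count matrix:

* **pseudobulk** — aggregate each gene to one value per individual (sum or
  mean over that individual's cells) and run a sample-level two-group Welch
  t-test on log2(value + 1).  The unit of replication is the individual.
* **pseudoreplication** — treat cells as independent replicates: cell-level
  Welch t ("Modified t"), a left-censored Tobit regression, and a two-part
  hurdle (detection + positive expression), optionally corrected with each
  cell's detection rate as a covariate.
* **cluster-aware** — Gaussian GEE with an exchangeable working correlation
  and robust (sandwich) standard errors, clusters = individuals ("GEE1").

Every result records a checksum of the input counts so that a benchmark run
can prove all methods saw identical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
import statsmodels.api as sm

from ._numerics import batched_logistic_deviance, batched_wls, tobit_fit, welch_t
from .simulate import SimulatedDataset

__all__ = [
    "ROSTER",
    "DEResult",
    "PseudobulkMatrix",
    "aggregate_pseudobulk",
    "normalize_cpm",
    "test_pseudobulk",
    "test_modified_t",
    "test_tobit",
    "test_two_part_hurdle",
    "test_gee1",
    "run_all_methods",
]

ROSTER = (
    "Pseudobulk: Mean",
    "Pseudobulk: Sum",
    "Modified t",
    "Tobit",
    "Two-part hurdle: Default",
    "Two-part hurdle: Corrected",
    "GEE1",
)


@dataclass
class DEResult:
    """Per-gene p-values and effect estimates from one method on one dataset."""

    method_name: str
    p_values: np.ndarray         # (n_genes,), NaN where a fit failed
    effect_estimates: np.ndarray # (n_genes,), log2-scale where defined
    n_failed: int
    dataset_checksum: str = ""

    def __post_init__(self) -> None:
        p = self.p_values
        finite = p[np.isfinite(p)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("p-values must lie in [0, 1]")


@dataclass
class PseudobulkMatrix:
    """Genes x individuals aggregate of a count matrix."""

    values: np.ndarray           # (n_genes, n_individuals)
    individual_group: np.ndarray # (n_individuals,) 'case' / 'control'
    aggregation: str             # 'mean' or 'sum'
    normalized: bool = False
    dataset_checksum: str = ""


def aggregate_pseudobulk(ds: SimulatedDataset, aggregation: str) -> PseudobulkMatrix:
    """Collapse counts to one column per individual by sum or mean over cells.

    Mean aggregation divides each individual's summed counts by that
    individual's own cell count, which makes it invariant to between-group
    differences in cells per individual; sum aggregation is not.
    """
    if aggregation not in ("mean", "sum"):
        raise ValueError("aggregation must be 'mean' or 'sum'")
    n_ind = ds.n_individuals
    cells_per = np.bincount(ds.cell_individual, minlength=n_ind)
    if np.any(cells_per == 0):
        raise ValueError("every individual must have at least one cell")
    # indicator (n_cells x n_ind) matmul does the grouped sum
    indicator = np.zeros((ds.n_cells, n_ind))
    indicator[np.arange(ds.n_cells), ds.cell_individual] = 1.0
    sums = ds.counts @ indicator
    values = sums / cells_per if aggregation == "mean" else sums
    return PseudobulkMatrix(values=values, individual_group=ds.individual_group,
                            aggregation=aggregation,
                            dataset_checksum=ds.checksum())


def normalize_cpm(pb: PseudobulkMatrix) -> PseudobulkMatrix:
    """Scale each individual's column to counts per million (depth removal)."""
    totals = pb.values.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("cannot CPM-normalize an individual with zero total counts")
    return PseudobulkMatrix(values=pb.values * 1e6 / totals,
                            individual_group=pb.individual_group,
                            aggregation=pb.aggregation, normalized=True,
                            dataset_checksum=pb.dataset_checksum)


def test_pseudobulk(pb: PseudobulkMatrix) -> DEResult:
    """Welch two-sample t-test per gene on log2(pseudobulk + 1), individuals as units."""
    case = pb.individual_group == "case"
    if case.sum() < 2 or (~case).sum() < 2:
        raise ValueError("need at least two individuals per group")
    y = np.log2(pb.values + 1.0)
    _, p, effect = welch_t(y[:, case], y[:, ~case])
    name = "Pseudobulk: Mean" if pb.aggregation == "mean" else "Pseudobulk: Sum"
    return DEResult(method_name=name, p_values=p, effect_estimates=effect,
                    n_failed=0, dataset_checksum=pb.dataset_checksum)


def test_modified_t(ds: SimulatedDataset) -> DEResult:
    """Cell-level Welch t-test on log2(count + 1), ignoring individual structure."""
    case = ds.cell_is_case
    y = np.log2(ds.counts + 1.0)
    _, p, effect = welch_t(y[:, case], y[:, ~case])
    return DEResult(method_name="Modified t", p_values=p, effect_estimates=effect,
                    n_failed=0, dataset_checksum=ds.checksum())


def test_tobit(ds: SimulatedDataset) -> DEResult:
    """Tobit (left-censored at zero) ML regression of log2(count + 1) on group,
    cells as units; Wald test on the group coefficient."""
    case = ds.cell_is_case.astype(float)
    X = np.column_stack([np.ones_like(case), case])
    Y = np.log2(ds.counts + 1.0)
    n_genes = ds.n_genes
    p = np.full(n_genes, np.nan)
    eff = np.full(n_genes, np.nan)
    n_failed = 0
    for g in range(n_genes):
        p[g], eff[g], ok = tobit_fit(X, Y[g])
        if not ok:
            n_failed += 1
    return DEResult(method_name="Tobit", p_values=p, effect_estimates=eff,
                    n_failed=n_failed, dataset_checksum=ds.checksum())


def test_two_part_hurdle(ds: SimulatedDataset, corrected: bool = False) -> DEResult:
    """Two-part hurdle test per gene, cells as units.

    Part A: logistic regression of detection (count > 0) on group.
    Part B: linear regression of log2(count) on group among detected cells.
    The combined statistic is the sum of the two likelihood-ratio chi-squares
    on the sum of their degrees of freedom; a degenerate part (no detection
    variation, or too few detected cells to identify the group effect)
    contributes zero of each.  ``corrected=True`` adds each cell's detection
    rate — the fraction of genes detected in that cell — as a covariate in
    both parts, the standard guard against cell-level technical variation.
    """
    counts = ds.counts
    n_genes, n_cells = counts.shape
    case = ds.cell_is_case.astype(float)
    D = (counts > 0).astype(float).T          # (n_cells, n_genes)
    n_det = D.sum(axis=0)

    cols_full = [np.ones(n_cells), case]
    cols_null = [np.ones(n_cells)]
    if corrected:
        cdr = D.mean(axis=1)  # per-cell detection rate over genes
        cols_full.append(cdr)
        cols_null.append(cdr)
    X_full = np.column_stack(cols_full)
    X_null = np.column_stack(cols_null)

    # Part A: detection LRT (skipped for genes detected in all or no cells)
    varying = (n_det > 0) & (n_det < n_cells)
    lr_a = np.zeros(n_genes)
    df_a = np.zeros(n_genes, dtype=int)
    if varying.any():
        Dv = D[:, varying]
        dev_full, _, ok_f = batched_logistic_deviance(X_full, Dv)
        dev_null, _, ok_n = batched_logistic_deviance(X_null, Dv)
        lr = np.clip(dev_null - dev_full, 0.0, None)
        good = ok_f & ok_n & np.isfinite(lr)
        lr_a[varying] = np.where(good, lr, 0.0)
        df_a[varying] = good.astype(int)

    # Part B: positive-expression LRT among detected cells (0/1 weights)
    with np.errstate(divide="ignore"):
        Ypos = np.where(counts.T > 0, np.log2(np.maximum(counts.T, 1)), 0.0)
    p_full = X_full.shape[1]
    enough = n_det > p_full  # need residual df for the variance estimate
    lr_b = np.zeros(n_genes)
    df_b = np.zeros(n_genes, dtype=int)
    eff = np.full(n_genes, np.nan)
    if enough.any():
        Ye = Ypos[:, enough]
        We = D[:, enough]
        beta_f, rss_f, ok_f = batched_wls(X_full, Ye, We)
        _, rss_n, ok_n = batched_wls(X_null, Ye, We)
        nd = n_det[enough]
        with np.errstate(divide="ignore", invalid="ignore"):
            lr = nd * np.log(rss_n / rss_f)
        good = ok_f & ok_n & np.isfinite(lr) & (rss_f > 1e-12)
        lr_b[enough] = np.where(good, np.clip(lr, 0.0, None), 0.0)
        df_b[enough] = good.astype(int)
        eff_e = np.where(good, beta_f[:, 1], np.nan)
        eff[enough] = eff_e

    chi2 = lr_a + lr_b
    df = df_a + df_b
    p = np.full(n_genes, np.nan)
    has_df = df > 0
    p[has_df] = scipy.stats.chi2.sf(chi2[has_df], df[has_df])
    # detected somewhere but both parts degenerate: no evidence, not a failure
    p[(~has_df) & (n_det > 0)] = 1.0
    n_failed = int(np.isnan(p).sum())
    name = "Two-part hurdle: Corrected" if corrected else "Two-part hurdle: Default"
    return DEResult(method_name=name, p_values=p, effect_estimates=eff,
                    n_failed=n_failed, dataset_checksum=ds.checksum())


def test_gee1(ds: SimulatedDataset) -> DEResult:
    """Gaussian GEE of log2(count + 1) on group with exchangeable working
    correlation, clusters = individuals, sandwich standard errors."""
    case = ds.cell_is_case.astype(float)
    X = np.column_stack([np.ones_like(case), case])
    Y = np.log2(ds.counts + 1.0)
    groups = ds.cell_individual
    n_genes = ds.n_genes
    p = np.full(n_genes, np.nan)
    eff = np.full(n_genes, np.nan)
    n_failed = 0
    for g in range(n_genes):
        y = Y[g]
        if np.ptp(y) == 0:  # constant response: no evidence, not a failure
            p[g], eff[g] = 1.0, 0.0
            continue
        try:
            fit = sm.GEE(y, X, groups=groups,
                         cov_struct=sm.cov_struct.Exchangeable(),
                         family=sm.families.Gaussian()).fit()
            coef, se = fit.params[1], fit.bse[1]
            tiny = 1e-10 * (np.std(y) + 1e-300)
            if se < tiny:
                # perfectly symmetric clusters: sandwich variance collapses
                # to rounding error; report the no-evidence verdict instead
                p[g] = 1.0 if abs(coef) < tiny else 0.0
                eff[g] = coef
            elif np.isfinite(fit.pvalues[1]):
                p[g] = fit.pvalues[1]
                eff[g] = coef
            else:
                n_failed += 1
        except Exception:
            n_failed += 1
    return DEResult(method_name="GEE1", p_values=p, effect_estimates=eff,
                    n_failed=n_failed, dataset_checksum=ds.checksum())


def run_all_methods(ds: SimulatedDataset, roster=ROSTER,
                    cpm_normalize: bool = False) -> dict[str, DEResult]:
    """Run every requested method on the identical counts matrix.

    Methods share no mutable state, so execution order cannot affect any
    p-value.  ``cpm_normalize`` applies counts-per-million scaling to the
    pseudobulk matrices before testing (off by default).
    """
    if not roster:
        raise ValueError("roster must be non-empty")
    unknown = set(roster) - set(ROSTER)
    if unknown:
        raise ValueError(f"unknown method name(s): {sorted(unknown)}")
    results: dict[str, DEResult] = {}
    for name in roster:
        if name == "Pseudobulk: Mean":
            pb = aggregate_pseudobulk(ds, "mean")
            results[name] = test_pseudobulk(normalize_cpm(pb) if cpm_normalize else pb)
        elif name == "Pseudobulk: Sum":
            pb = aggregate_pseudobulk(ds, "sum")
            results[name] = test_pseudobulk(normalize_cpm(pb) if cpm_normalize else pb)
        elif name == "Modified t":
            results[name] = test_modified_t(ds)
        elif name == "Tobit":
            results[name] = test_tobit(ds)
        elif name == "Two-part hurdle: Default":
            results[name] = test_two_part_hurdle(ds, corrected=False)
        elif name == "Two-part hurdle: Corrected":
            results[name] = test_two_part_hurdle(ds, corrected=True)
        elif name == "GEE1":
            results[name] = test_gee1(ds)
    return results
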