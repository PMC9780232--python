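"""Factorial benchmarking of DE strategies on shared simulated datasets.

For every grid point (individuals per group x cells per individual) and run,
one dataset is simulated from an iteration seed derived from the master seed,
and *every* method in the roster is scored on that same matrix — the fair
comparison the seeding contract exists for.  Iteration seeds are pre-derived,
so results are independent of execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics
from .methods import ROSTER, run_all_methods
from .simulate import SimParams, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["GridSpec", "run_grid", "run_roc_study", "run_imbalanced_study",
           "summarize", "iteration_seed"]

METRIC_COLUMNS = ("mcc", "type1", "sensitivity", "auc")


@dataclasses.dataclass
class GridSpec:
    """Design of a benchmark experiment.

    ``individuals_levels`` are per-group sizes; ``cells_levels`` are cells per
    individual (balanced).  ``base_params`` carries the simulator settings
    shared across grid points (fold-change bounds, dispersion, dropout, ...).
    """

    individuals_levels: tuple[int, ...] = (5, 10, 20, 30, 40)
    cells_levels: tuple[int, ...] = (50, 100, 250, 500)
    runs_per_cell: int = 50
    prop_de: float = 0.1
    alpha: float = 0.05
    roster: tuple[str, ...] = ROSTER
    base_params: SimParams = dataclasses.field(default_factory=SimParams)
    master_seed: int = 0
    cpm_normalize: bool = False

    def __post_init__(self) -> None:
        if self.runs_per_cell < 1:
            raise ValueError("runs_per_cell must be >= 1")
        if any(v < 1 for v in tuple(self.individuals_levels) + tuple(self.cells_levels)):
            raise ValueError("grid levels must be positive")


def iteration_seed(master_seed: int, n_individuals: int, cells_case: int,
                   cells_control: int, run: int) -> int:
    """Deterministic per-iteration seed (< 2^31) keyed by the design point."""
    ss = np.random.SeedSequence(
        entropy=master_seed,
        spawn_key=(n_individuals, cells_case, cells_control, run))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def _iteration_rows(spec: GridSpec, n_individuals: int, cells_case: int,
                    cells_control: int, run: int) -> list[dict]:
    seed = iteration_seed(spec.master_seed, n_individuals, cells_case,
                          cells_control, run)
    params = dataclasses.replace(
        spec.base_params, prop_de=spec.prop_de,
        n_cases=n_individuals, n_controls=n_individuals,
        cells_per_individual_case=cells_case,
        cells_per_individual_control=cells_control,
        master_seed=seed)
    ds = simulate_dataset(params)
    rows = []
    for method in spec.roster:
        base = dict(n_individuals=n_individuals, n_cells_case=cells_case,
                    n_cells_control=cells_control, run=run, method=method,
                    seed=seed)
        try:
            res = run_all_methods(ds, roster=(method,),
                                  cpm_normalize=spec.cpm_normalize)[method]
            c = metrics.confusion_at_alpha(res.p_values, ds.truth, spec.alpha)
            row = dict(base, mcc=metrics.mcc(c), type1=metrics.type1_error(c),
                       sensitivity=metrics.sensitivity(c),
                       auc=np.nan, n_failed=res.n_failed,
                       checksum=res.dataset_checksum)
            if ds.truth.is_de.any() and not ds.truth.is_de.all():
                row["auc"] = metrics.roc_curve(res.p_values, ds.truth.is_de).auc
        except Exception:
            logger.exception("method %s failed on iteration (%d ind, %d/%d cells, run %d)",
                             method, n_individuals, cells_case, cells_control, run)
            row = dict(base, mcc=np.nan, type1=np.nan, sensitivity=np.nan,
                       auc=np.nan, n_failed=params.n_genes, checksum="")
        rows.append(row)
    return rows


def run_grid(spec: GridSpec) -> pd.DataFrame:
    """Run the full balanced factorial: one simulated dataset per iteration,
    every roster method scored on it.  Long-format table, one row per
    (grid point, run, method)."""
    rows: list[dict] = []
    for n_ind in spec.individuals_levels:
        for cells in spec.cells_levels:
            for run in range(spec.runs_per_cell):
                rows.extend(_iteration_rows(spec, n_ind, cells, cells, run))
    return pd.DataFrame(rows)


def run_imbalanced_study(spec: GridSpec, cells_case: int,
                         cells_control: int) -> pd.DataFrame:
    """Benchmark with unequal cells per individual between the groups
    (e.g. 150 vs 50); reduces exactly to a `run_grid` point when equal."""
    rows: list[dict] = []
    for n_ind in spec.individuals_levels:
        for run in range(spec.runs_per_cell):
            rows.extend(_iteration_rows(spec, n_ind, cells_case, cells_control, run))
    return pd.DataFrame(rows)


def run_roc_study(spec: GridSpec,
                  prop_de_levels: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3),
                  n_individuals: int = 20, n_cells: int = 100,
                  runs: int = 50, target_fpr: float = 0.05):
    """Pooled ROC study over DE-gene proportions.

    For each proportion, `runs` datasets are simulated and each method's
    p-values are pooled across runs *before* the ROC is built, giving one
    curve per (proportion, method).  Returns (curves, summary) where curves
    maps (prop_de, method) -> ROCCurve and summary is a tidy table with AUC
    and sensitivity at the target FPR.
    """
    curves: dict[tuple[float, str], metrics.ROCCurve] = {}
    rows = []
    for prop_de in prop_de_levels:
        pooled_p = {m: [] for m in spec.roster}
        pooled_truth = []
        for run in range(runs):
            seed = iteration_seed(spec.master_seed, n_individuals, n_cells,
                                  n_cells, run)
            params = dataclasses.replace(
                spec.base_params, prop_de=prop_de,
                n_cases=n_individuals, n_controls=n_individuals,
                cells_per_individual_case=n_cells,
                cells_per_individual_control=n_cells,
                master_seed=seed)
            ds = simulate_dataset(params)
            res = run_all_methods(ds, roster=spec.roster,
                                  cpm_normalize=spec.cpm_normalize)
            for m in spec.roster:
                pooled_p[m].append(res[m].p_values)
            pooled_truth.append(ds.truth.is_de)
        truth = np.concatenate(pooled_truth)
        for m in spec.roster:
            p = np.concatenate(pooled_p[m])
            curve = metrics.roc_curve(p, truth)
            curves[(prop_de, m)] = curve
            rows.append(dict(prop_de=prop_de, method=m, auc=curve.auc,
                             sensitivity_at_target=metrics.sensitivity_at_fpr(
                                 curve, target_fpr),
                             target_fpr=target_fpr, runs=runs))
    return curves, pd.DataFrame(rows)


def summarize(table: pd.DataFrame, out_dir: str | Path | None = None
              ) -> pd.DataFrame:
    """Per-(method, grid point) mean and Monte-Carlo standard error of each
    metric; optionally writes the summary TSV and an MCC figure."""
    if table.empty:
        raise ValueError("benchmark table is empty")
    keys = ["method", "n_individuals", "n_cells_case", "n_cells_control"]
    records = []
    for key, sub in table.groupby(keys, sort=True):
        rec = dict(zip(keys, key))
        rec["n_runs"] = len(sub)
        for col in METRIC_COLUMNS:
            vals = sub[col].to_numpy(dtype=float)
            good = np.isfinite(vals)
            rec[f"{col}_mean"] = vals[good].mean() if good.any() else np.nan
            # population sd: SE halves exactly when the table is duplicated
            rec[f"{col}_se"] = (vals[good].std(ddof=0) / np.sqrt(good.sum())
                                if good.any() else np.nan)
            rec[f"{col}_n_missing"] = int((~good).sum())
        rec["all_missing"] = bool(np.all(~np.isfinite(
            sub[list(METRIC_COLUMNS)].to_numpy(dtype=float))))
        records.append(rec)
    summary = pd.DataFrame(records)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        _plot_mcc(summary, out / "mcc_vs_cells.png")
    return summary


def _plot_mcc(summary: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    balanced = summary[summary.n_cells_case == summary.n_cells_control]
    ind_levels = sorted(balanced.n_individuals.unique())
    fig, axes = plt.subplots(1, max(len(ind_levels), 1),
                             figsize=(4 * max(len(ind_levels), 1), 3.2),
                             sharey=True, squeeze=False)
    for ax, n_ind in zip(axes[0], ind_levels):
        sub = balanced[balanced.n_individuals == n_ind]
        for method, ms in sub.groupby("method"):
            ms = ms.sort_values("n_cells_case")
            ax.errorbar(ms.n_cells_case, ms.mcc_mean, yerr=ms.mcc_se,
                        marker="o", label=method)
        ax.set_title(f"{n_ind} individuals / group")
        ax.set_xlabel("cells per individual")
    axes[0][0].set_ylabel("mean MCC")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_manifest(spec: GridSpec, table: pd.DataFrame, out_dir: str | Path) -> None:
    """Run manifest: design, seeds and dataset checksums for reproducibility."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "spec": {**dataclasses.asdict(spec),
                 "base_params": spec.base_params.to_dict()},
        "iterations": table[["n_individuals", "n_cells_case", "n_cells_control",
                             "run", "seed", "checksum"]]
        .drop_duplicates().to_dict(orient="records"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
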