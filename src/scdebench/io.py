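"""On-disk representation of simulated datasets and method results.

Counts are MatrixMarket integer sparse (genes x cells, 1-based per the MTX
standard), metadata and truth are plain TSV, and the simulation parameters a
YAML config — all text formats, round-tripping losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .simulate import GeneTruth, SimParams, SimulatedDataset

COUNTS_FILE = "counts.mtx"
CELLS_FILE = "cell_metadata.tsv"
TRUTH_FILE = "gene_truth.tsv"
PARAMS_FILE = "params.yaml"


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> Path:
    """Write a dataset as MTX counts + cell metadata TSV + truth TSV + params YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sparse = scipy.sparse.coo_matrix(ds.counts)
    scipy.io.mmwrite(str(out / COUNTS_FILE), sparse, field="integer")

    group_per_cell = ds.individual_group[ds.cell_individual]
    pd.DataFrame({
        "cell_id": ds.cell_ids,
        "individual_id": [ds.individual_ids[i] for i in ds.cell_individual],
        "group": group_per_cell,
    }).to_csv(out / CELLS_FILE, sep="\t", index=False)

    pd.DataFrame({
        "gene_id": ds.gene_ids,
        "is_de": ds.truth.is_de.astype(int),
        "fold_change": ds.truth.fold_change,
    }).to_csv(out / TRUTH_FILE, sep="\t", index=False)

    cfg = ds.params.to_dict()
    cfg["seed_used"] = ds.seed_used
    with open(out / PARAMS_FILE, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return out


def read_dataset(in_dir: str | Path) -> SimulatedDataset:
    """Read a dataset written by :func:`write_dataset` (or external data in the
    same layout; truth and params files are optional for external counts)."""
    src = Path(in_dir)
    counts = np.asarray(scipy.io.mmread(str(src / COUNTS_FILE)).todense(),
                        dtype=np.int32)
    cells = pd.read_csv(src / CELLS_FILE, sep="\t", dtype=str)

    individual_ids = list(dict.fromkeys(cells["individual_id"]))
    ind_index = {ind: i for i, ind in enumerate(individual_ids)}
    cell_individual = cells["individual_id"].map(ind_index).to_numpy()
    group_by_ind = cells.drop_duplicates("individual_id").set_index("individual_id")["group"]
    individual_group = np.array([group_by_ind[i] for i in individual_ids])

    truth_path = src / TRUTH_FILE
    if truth_path.exists():
        tr = pd.read_csv(truth_path, sep="\t")
        truth = GeneTruth(is_de=tr["is_de"].to_numpy(dtype=bool),
                          fold_change=tr["fold_change"].to_numpy(dtype=float))
        gene_ids = tr["gene_id"].astype(str).tolist()
    else:
        truth = GeneTruth(is_de=np.zeros(counts.shape[0], dtype=bool),
                          fold_change=np.ones(counts.shape[0]))
        gene_ids = [f"gene{g}" for g in range(counts.shape[0])]

    params_path = src / PARAMS_FILE
    seed_used = 0
    if params_path.exists():
        with open(params_path) as fh:
            cfg = yaml.safe_load(fh)
        seed_used = int(cfg.pop("seed_used", cfg.get("master_seed", 0)))
        params = SimParams.from_dict(cfg)
    else:
        n_case = int((individual_group == "case").sum())
        n_ctrl = len(individual_group) - n_case
        params = SimParams(n_genes=counts.shape[0], n_cases=max(n_case, 1),
                           n_controls=max(n_ctrl, 1))

    return SimulatedDataset(
        counts=counts,
        cell_individual=cell_individual,
        individual_group=individual_group,
        truth=truth,
        params=params,
        seed_used=seed_used,
        gene_ids=gene_ids,
        cell_ids=cells["cell_id"].astype(str).tolist(),
        individual_ids=individual_ids,
    )


def write_de_result(result, out_path: str | Path, gene_ids: list[str]) -> None:
    """Per-method output TSV: gene_id, p_value, effect_estimate, fit_ok."""
    pd.DataFrame({
        "gene_id": gene_ids,
        "p_value": result.p_values,
        "effect_estimate": result.effect_estimates,
        "fit_ok": (~np.isnan(result.p_values)).astype(int),
    }).to_csv(out_path, sep="\t", index=False, na_rep="NA")
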