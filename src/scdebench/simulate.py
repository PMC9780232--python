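"""Hierarchical two-group single-cell count simulator with known differential expression.

The generative model mirrors the structure of droplet scRNA-seq data from a
case/control cohort: genes are simulated independently, cells are nested
within individuals, and individuals carry a shared random effect that makes
cells from the same donor correlated.  For gene ``g`` with baseline mean
``mu_g`` (drawn log-normally across genes):

* individual ``i`` gets a log-scale random effect ``delta_i ~ N(0, sigma_ind^2)``
  and an individual-level mean ``m_i = mu_g * exp(delta_i)``, multiplied by the
  gene's fold change when the individual is a case;
* each cell of individual ``i`` draws a latent count from a negative binomial
  with mean ``m_i`` and dispersion ``phi`` (variance ``m + phi m^2``);
* the observed count is zeroed with dropout probability
  ``logistic(a - b * log(m_i))``, so lowly expressed genes drop out more.

Every random draw comes from a named substream derived from a single master
seed, keyed by purpose and gene index.  Regenerating with the same parameters
and master seed is bit-identical, and all downstream tests consume the same
matrix — the simulator is built so that competing analysis strategies can be
compared on literally identical data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SimParams",
    "GeneTruth",
    "SimulatedDataset",
    "sample_fold_changes",
    "simulate_gene",
    "simulate_dataset",
]

# Substream purposes (spawn-key prefixes off the master seed).
_STREAM_GENE_MEANS = 0
_STREAM_DE_PERMUTATION = 1
_STREAM_FOLD_CHANGES = 2
_STREAM_GENE_COUNTS = 3


@dataclass(frozen=True)
class SimParams:
    """Parameters of the hierarchical count simulator.

    Log-scale parameters (``grand_mean_log_mu``, ``grand_mean_log_sd``,
    ``sigma_ind``) are on the natural-log scale.  ``sigma_ind = 0`` removes
    the donor random effect, making cells exchangeable across individuals.
    ``nb_dispersion`` is the negative-binomial dispersion ``phi`` in
    ``Var = m + phi * m^2``; zero collapses to Poisson.  Dropout probability
    for a cell with individual-level mean ``m`` is
    ``sigmoid(dropout_intercept - dropout_slope * log(m))``.
    """

    n_genes: int = 10_000
    prop_de: float = 0.1
    n_cases: int = 20
    n_controls: int = 20
    cells_per_individual_case: int = 100
    cells_per_individual_control: int = 100
    fc_min: float = 1.1
    fc_max: float = 10.0
    grand_mean_log_mu: float = float(np.log(2.0))
    grand_mean_log_sd: float = 1.0
    sigma_ind: float = 0.3
    nb_dispersion: float = 0.5
    dropout_intercept: float = -1.0
    dropout_slope: float = 0.5
    fc_log_uniform: bool = False
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be a positive integer")
        if not 0.0 <= self.prop_de <= 1.0:
            raise ValueError("prop_de must lie in [0, 1]")
        for name in ("n_cases", "n_controls", "cells_per_individual_case",
                     "cells_per_individual_control"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not self.fc_min > 1.0:
            raise ValueError("fc_min must exceed 1")
        if self.fc_max < self.fc_min:
            raise ValueError("fc_max must be >= fc_min")
        if self.sigma_ind < 0:
            raise ValueError("sigma_ind must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.master_seed < 0:
            raise ValueError("master_seed must be non-negative")

    @property
    def n_individuals(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_cells(self) -> int:
        return (self.n_cases * self.cells_per_individual_case
                + self.n_controls * self.cells_per_individual_control)

    @property
    def n_de(self) -> int:
        # round-half-even would make DEG counts surprising; use round-half-up
        return int(np.floor(self.n_genes * self.prop_de + 0.5))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(**d)


@dataclass
class GeneTruth:
    """Per-gene ground truth: DE flag and signed fold change (1.0 when null)."""

    is_de: np.ndarray        # bool, (n_genes,)
    fold_change: np.ndarray  # float, (n_genes,)

    def __post_init__(self) -> None:
        self.is_de = np.asarray(self.is_de, dtype=bool)
        self.fold_change = np.asarray(self.fold_change, dtype=float)
        if self.is_de.shape != self.fold_change.shape:
            raise ValueError("is_de and fold_change must have the same length")
        if np.any((self.fold_change == 1.0) != ~self.is_de):
            raise ValueError("fold_change must be 1.0 exactly for non-DE genes")

    @property
    def n_de(self) -> int:
        return int(self.is_de.sum())


@dataclass
class SimulatedDataset:
    """A simulated genes x cells count matrix with its nesting structure and truth."""

    counts: np.ndarray           # (n_genes, n_cells) non-negative ints
    cell_individual: np.ndarray  # (n_cells,) int codes into individual_ids
    individual_group: np.ndarray # (n_individuals,) 'case' / 'control'
    truth: GeneTruth
    params: SimParams
    seed_used: int
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_genes, n_cells = self.counts.shape
        if not self.gene_ids:
            self.gene_ids = [f"gene{g}" for g in range(n_genes)]
        if not self.cell_ids:
            self.cell_ids = [f"cell{c}" for c in range(n_cells)]
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(len(self.individual_group))]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_individuals(self) -> int:
        return len(self.individual_group)

    @property
    def cell_is_case(self) -> np.ndarray:
        """Boolean per cell: does the cell belong to a case individual."""
        return (self.individual_group == "case")[self.cell_individual]

    def checksum(self) -> str:
        """SHA-256 of the counts matrix; identical input for every DE method."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.counts, dtype=np.int64).tobytes())
        h.update(str(self.counts.shape).encode())
        return h.hexdigest()


def _substream(master_seed: int, *key: int) -> np.random.Generator:
    """Named substream of the master seed; isolation across purposes and genes."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return np.random.default_rng(ss)


def sample_fold_changes(n_de: int, fc_min: float, fc_max: float,
                        rng: np.random.Generator,
                        log_uniform: bool = False) -> np.ndarray:
    """Draw signed fold changes for DE genes.

    Magnitudes are uniform on [fc_min, fc_max] (or log-uniform when requested);
    each gene is up- (f = m) or down-regulated (f = 1/m) with probability 1/2.
    Draws are consumed pairwise per gene so that the first k values are a
    stable prefix regardless of n_de.
    """
    if n_de < 0:
        raise ValueError("n_de must be non-negative")
    if not fc_min > 1.0:
        raise ValueError("fc_min must exceed 1")
    if fc_max < fc_min:
        raise ValueError("fc_max must be >= fc_min")
    if n_de == 0:
        return np.empty(0, dtype=float)
    u = rng.uniform(size=(n_de, 2))
    if log_uniform:
        mag = np.exp(np.log(fc_min) + u[:, 0] * (np.log(fc_max) - np.log(fc_min)))
    else:
        mag = fc_min + u[:, 0] * (fc_max - fc_min)
    down = u[:, 1] < 0.5
    fc = np.where(down, 1.0 / mag, mag)
    return fc


def simulate_gene(gene_mean: float, fold_change: float,
                  cell_individual: np.ndarray, individual_is_case: np.ndarray,
                  params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Simulate one gene's counts over all cells.

    Draw order is fixed (individual effects, then latent counts, then dropout)
    so a gene's counts depend only on its own substream state.
    """
    if gene_mean <= 0:
        raise ValueError("gene_mean must be positive")
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    n_ind = individual_is_case.size
    delta = rng.normal(0.0, params.sigma_ind, size=n_ind) if params.sigma_ind > 0 \
        else np.zeros(n_ind)
    m_ind = gene_mean * np.exp(delta)
    m_ind = np.where(individual_is_case, m_ind * fold_change, m_ind)
    m_cell = m_ind[cell_individual]

    phi = params.nb_dispersion
    if phi > 0:
        # gamma-Poisson mixture: shape 1/phi, mean m  =>  Var = m + phi m^2
        lam = rng.gamma(shape=1.0 / phi, scale=phi * m_cell)
        latent = rng.poisson(lam)
    else:
        latent = rng.poisson(m_cell)

    logit_pi = params.dropout_intercept - params.dropout_slope * np.log(m_cell)
    pi = 1.0 / (1.0 + np.exp(-logit_pi))
    dropped = rng.uniform(size=m_cell.size) < pi
    counts = np.where(dropped, 0, latent)
    return counts.astype(np.int64)


def _design(params: SimParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Individual/group layout: cases first, then controls."""
    group = np.array(["case"] * params.n_cases + ["control"] * params.n_controls)
    cells_per = np.array(
        [params.cells_per_individual_case] * params.n_cases
        + [params.cells_per_individual_control] * params.n_controls
    )
    cell_individual = np.repeat(np.arange(params.n_individuals), cells_per)
    return cell_individual, group, cells_per


def simulate_dataset(params: SimParams) -> SimulatedDataset:
    """Simulate a full dataset: baselines, truth assignment, per-gene counts.

    DE genes are the first ``round(n_genes * prop_de)`` indices of a seeded
    permutation, so the DE count is exact rather than binomial.  Each gene's
    counts come from a dedicated substream keyed by its index, which makes the
    counts of a gene invariant to changes in the truth assignment of *other*
    genes (stream isolation).
    """
    seed = params.master_seed
    n_genes = params.n_genes

    mean_rng = _substream(seed, _STREAM_GENE_MEANS)
    gene_means = np.exp(mean_rng.normal(params.grand_mean_log_mu,
                                        params.grand_mean_log_sd, size=n_genes))

    perm_rng = _substream(seed, _STREAM_DE_PERMUTATION)
    perm = perm_rng.permutation(n_genes)
    n_de = params.n_de
    de_genes = perm[:n_de]

    fc_rng = _substream(seed, _STREAM_FOLD_CHANGES)
    fc_de = sample_fold_changes(n_de, params.fc_min, params.fc_max, fc_rng,
                                log_uniform=params.fc_log_uniform)
    fold_change = np.ones(n_genes)
    fold_change[de_genes] = fc_de
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_genes] = True

    cell_individual, group, _ = _design(params)
    ind_is_case = group == "case"

    counts = np.empty((n_genes, cell_individual.size), dtype=np.int32)
    for g in range(n_genes):
        rng = _substream(seed, _STREAM_GENE_COUNTS, g)
        counts[g] = simulate_gene(gene_means[g], fold_change[g],
                                  cell_individual, ind_is_case, params, rng)

    ind_ids = [f"{'case' if ind_is_case[i] else 'ctrl'}{i}" for i in range(group.size)]
    return SimulatedDataset(
        counts=counts,
        cell_individual=cell_individual,
        individual_group=group,
        truth=GeneTruth(is_de=is_de, fold_change=fold_change),
        params=params,
        seed_used=seed,
        individual_ids=ind_ids,
    )
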