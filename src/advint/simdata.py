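"""Synthetic single-cell expression data with known key genes.

The generator emulates the statistical structure of GRN-driven simulators
such as SERGIO without reproducing their stochastic dynamics: each cell type
has a set of designated master-regulator ("key") genes whose mean expression
is elevated by a configurable fold in that type; regulatory edges propagate a
fraction of that elevation to target genes; counts are drawn from a negative
binomial (gamma-Poisson) with configurable overdispersion and then thinned by
Bernoulli dropout. The master-regulator list is exported as the ground truth
against which interpretability methods are scored.

Data are carried as :class:`anndata.AnnData` with cells in rows, the cell
type in ``obs["cell_type"]`` and gene identifiers in ``var_names``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .errors import DimensionError, LabelError, ParameterError

LABEL_KEY = "cell_type"

__all__ = [
    "SimConfig",
    "GRNSpec",
    "default_grn",
    "simulate_dataset",
    "expected_mean_matrix",
    "subsample_cell_types",
    "LABEL_KEY",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic expression generator.

    Defaults reproduce the packaged reference dataset: 2700 cells by
    1200 genes over nine equally sized cell types with 65 key genes.
    """

    n_cells: int = 2700
    n_genes: int = 1200
    n_types: int = 9
    n_key_genes: int = 65
    baseline_mean: float = 2.0  # mean counts of an unregulated gene
    fold_elevation: float = 5.0  # key-gene mean multiplier in its own type
    propagation_strength: float = 0.5  # fraction of elevation passed to targets
    nb_dispersion: float = 0.3  # var = mu + dispersion * mu^2
    dropout_rate: float = 0.3  # Bernoulli zero-inflation probability
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells, self.n_genes, self.n_types, self.n_key_genes) < 1:
            raise ParameterError("counts must be positive")
        if self.n_key_genes > self.n_genes:
            raise ParameterError("n_key_genes cannot exceed n_genes")
        if self.n_types > self.n_cells:
            raise ParameterError("need at least one cell per type")
        if self.baseline_mean <= 0:
            raise ParameterError("baseline_mean must be > 0")
        if self.fold_elevation <= 1:
            raise ParameterError("fold_elevation must be > 1")
        if self.propagation_strength < 0 or not math.isfinite(self.propagation_strength):
            raise ParameterError("propagation_strength must be finite and >= 0")
        if self.nb_dispersion < 0:
            raise ParameterError("nb_dispersion must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ParameterError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class GRNSpec:
    """Master regulators per cell type and signed regulator->target edges.

    ``masters_by_type[t]`` lists gene indices that are key genes of type
    ``t``; each key gene belongs to exactly one type. ``edges`` are
    ``(regulator, target, effect)`` triples with dimensionless effect
    multipliers; the graph is a bipartite regulator->target fan-out, hence
    acyclic by construction.
    """

    masters_by_type: tuple[tuple[int, ...], ...]
    edges: tuple[tuple[int, int, float], ...] = field(default_factory=tuple)

    @property
    def key_genes(self) -> list[tuple[int, int]]:
        """(gene index, type index) pairs, grouped by cell type."""
        return [(g, t) for t, genes in enumerate(self.masters_by_type) for g in genes]

    def validate(self, config: SimConfig) -> None:
        if len(self.masters_by_type) != config.n_types:
            raise DimensionError(
                f"GRN specifies {len(self.masters_by_type)} types, "
                f"config expects {config.n_types}"
            )
        flat = [g for genes in self.masters_by_type for g in genes]
        if len(flat) != len(set(flat)):
            raise DimensionError("a key gene is a master of more than one type")
        if len(flat) != config.n_key_genes:
            raise DimensionError(
                f"GRN has {len(flat)} master regulators, config expects "
                f"{config.n_key_genes}"
            )
        masters = set(flat)
        for reg, tgt, effect in self.edges:
            if not 0 <= tgt < config.n_genes or not 0 <= reg < config.n_genes:
                raise DimensionError(f"edge ({reg}, {tgt}) outside gene index range")
            if reg not in masters:
                raise DimensionError(f"edge regulator {reg} is not a master gene")
            if tgt in masters:
                raise DimensionError(f"edge target {tgt} is itself a master gene")
            if not math.isfinite(effect):
                raise DimensionError("edge effect sizes must be finite")


def default_grn(config: SimConfig) -> GRNSpec:
    """Deterministic default network for a given configuration.

    Key genes are spread as evenly as possible over the cell types (at the
    packaged defaults: eight types with 7 masters, one with 9, totalling 65)
    and each master regulates ``n_targets`` disjoint downstream genes with
    effect +1, as long as spare genes are available.
    """
    base, extra = divmod(config.n_key_genes, config.n_types)
    masters: list[tuple[int, ...]] = []
    cursor = 0
    for t in range(config.n_types):
        # the remainder is folded into the final type, so at the packaged
        # defaults the split is 8 types x 7 masters + 1 type x 9
        take = base + (extra if t == config.n_types - 1 else 0)
        masters.append(tuple(range(cursor, cursor + take)))
        cursor += take

    n_targets = 5
    edges: list[tuple[int, int, float]] = []
    tgt = cursor
    for genes in masters:
        for g in genes:
            for _ in range(n_targets):
                if tgt >= config.n_genes:
                    break
                edges.append((g, tgt, 1.0))
                tgt += 1
    return GRNSpec(masters_by_type=tuple(masters), edges=tuple(edges))


def _type_sizes(n_cells: int, n_types: int) -> list[int]:
    base, extra = divmod(n_cells, n_types)
    return [base + (1 if t < extra else 0) for t in range(n_types)]


def expected_mean_matrix(config: SimConfig, grn: GRNSpec) -> np.ndarray:
    """Closed-form pre-dropout mean counts, one row per cell type.

    Key gene of type t: ``baseline * fold`` in t, ``baseline`` elsewhere.
    Target gene: ``baseline * (1 + propagation * sum of signed parental
    elevations)`` where a parent contributes ``effect * (fold - 1)`` in the
    type it masters. Unregulated genes sit at ``baseline`` everywhere.
    """
    mu = np.full((config.n_types, config.n_genes), config.baseline_mean)
    master_type = {g: t for t, genes in enumerate(grn.masters_by_type) for g in genes}
    for g, t in master_type.items():
        mu[t, g] = config.baseline_mean * config.fold_elevation
    for reg, tgt, effect in grn.edges:
        t = master_type[reg]
        mu[t, tgt] += (
            config.baseline_mean
            * config.propagation_strength
            * effect
            * (config.fold_elevation - 1.0)
        )
    return np.clip(mu, 0.0, None)


def simulate_dataset(
    config: SimConfig | None = None, grn: GRNSpec | None = None
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Draw a labeled count matrix and its key-gene ground truth.

    Returns an :class:`~anndata.AnnData` (cells x genes, raw counts, labels
    in ``obs["cell_type"]``) and a two-column frame ``(gene, cell_type)``
    listing the designated key genes. Identical config (including seed)
    yields bitwise-identical output.
    """
    config = config or SimConfig()
    grn = grn or default_grn(config)
    grn.validate(config)

    rng = np.random.default_rng(config.seed)
    mu_types = expected_mean_matrix(config, grn)
    sizes = _type_sizes(config.n_cells, config.n_types)

    mu_cells = np.repeat(mu_types, sizes, axis=0)
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mu_cells / shape)
    else:
        lam = mu_cells
    counts = rng.poisson(lam).astype(np.float64)
    if config.dropout_rate > 0:
        counts *= rng.random(counts.shape) >= config.dropout_rate

    type_names = [f"CT{t + 1}" for t in range(config.n_types)]
    labels = np.repeat(type_names, sizes)
    obs = pd.DataFrame(
        {LABEL_KEY: pd.Categorical(labels, categories=type_names)},
        index=[f"C{i:04d}" for i in range(config.n_cells)],
    )
    var = pd.DataFrame(index=[f"G{j:04d}" for j in range(config.n_genes)])
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.uns["sim_config"] = {k: getattr(config, k) for k in config.__dataclass_fields__}

    truth = pd.DataFrame(
        [(var.index[g], type_names[t]) for g, t in grn.key_genes],
        columns=["gene", "cell_type"],
    )
    return adata, truth


def subsample_cell_types(
    adata: ad.AnnData,
    types: list[str],
    removal_fraction: float,
    seed: int = 0,
) -> ad.AnnData:
    """Remove a fraction of cells from the named types (class imbalance).

    For each named type, ``ceil((1 - removal_fraction) * n)`` cells are
    retained (never silently emptying a type); other types are untouched and
    the relative order of retained cells is preserved.
    """
    if not 0 <= removal_fraction <= 1:
        raise ParameterError("removal_fraction must lie in [0, 1]")
    labels = adata.obs[LABEL_KEY].astype(str).to_numpy()
    known = set(labels)
    for t in types:
        if t not in known:
            raise LabelError(f"unknown cell type {t!r}")

    rng = np.random.default_rng(seed)
    keep = np.ones(adata.n_obs, dtype=bool)
    for t in types:
        idx = np.flatnonzero(labels == t)
        # round before ceil so 0.15 * 60 does not become ceil(9.0000000002)
        n_keep = math.ceil(round((1.0 - removal_fraction) * idx.size, 9))
        drop = rng.choice(idx, size=idx.size - n_keep, replace=False)
        keep[drop] = False
    return adata[keep].copy()
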