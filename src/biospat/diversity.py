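"""Alpha, beta and phylogenetic diversity indices on community matrices.

Beta diversity follows the Sørensen-based partition: total dissimilarity
(Sørensen) = turnover (Simpson) + nestedness, element-wise.  Phylogenetic
variants (PhyloSor family) replace shared/unique species counts with
shared/unique branch lengths of the sites' rooted spanning subtrees.
Faith PD is rooted: the path to the root is part of every site's subtree.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DroppedDataWarning,
    EmptyInputError,
    UndefinedStatisticError,
)
from .io.trees import Phylogeny
from .tiling import CommunityMatrix


@dataclass
class SiteIndexTable:
    """Per-site values of one diversity index; NaN marks undefined sites."""

    site_ids: np.ndarray
    values: np.ndarray
    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.site_ids = np.asarray(self.site_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.site_ids) != len(self.values):
            raise ConfigError("site_ids and values must have equal length")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.site_ids, name=self.name).rename_axis(
            "cell_id"
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_series().to_csv(path)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise site dissimilarities in [0, 1]."""

    site_ids: np.ndarray
    matrix: np.ndarray
    metric: str

    def __post_init__(self):
        self.site_ids = np.asarray(self.site_ids)
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.site_ids):
            raise ConfigError("dissimilarity matrix shape mismatch")
        if not np.allclose(m, m.T, atol=1e-12, equal_nan=True):
            raise ConfigError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ConfigError("dissimilarity diagonal must be zero")
        finite = m[np.isfinite(m)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ConfigError("dissimilarities must lie in [0, 1]")
        self.matrix = np.clip(m, 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.site_ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.site_ids, columns=self.site_ids)

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().rename_axis("cell_id").to_csv(path)


@dataclass
class BetaPartition:
    """Total dissimilarity and its turnover/nestedness components."""

    total: DissimilarityMatrix
    turnover: DissimilarityMatrix
    nestedness: DissimilarityMatrix


def _require_nonempty(cm: CommunityMatrix):
    if cm.n_sites == 0 or cm.n_species == 0:
        raise EmptyInputError("empty community matrix")


def richness(cm: CommunityMatrix) -> SiteIndexTable:
    """Species count per site."""
    _require_nonempty(cm)
    return SiteIndexTable(cm.site_ids, cm.incidence.sum(axis=1).astype(float), "SR")


def rarefied_richness(
    cm: CommunityMatrix, n: int, reps: int = 100, seed: int | None = None
) -> SiteIndexTable:
    """Mean species count over ``reps`` without-replacement draws of ``n`` records.

    Sites with fewer than ``n`` records are reported as missing, never 0.
    """
    _require_nonempty(cm)
    if n < 1 or reps < 1:
        raise ConfigError("n and reps must be >= 1")
    rng = np.random.default_rng(seed)
    values = np.full(cm.n_sites, np.nan)
    for i in range(cm.n_sites):
        counts = cm.n_records[i]
        total = int(counts.sum())
        if total < n:
            continue
        records = np.repeat(np.arange(cm.n_species), counts)
        if total == n:
            values[i] = float(len(np.unique(records)))
            continue
        hits = 0
        for _ in range(reps):
            draw = rng.choice(records, size=n, replace=False)
            hits += len(np.unique(draw))
        values[i] = hits / reps
    if not np.isfinite(values).any():
        warnings.warn(
            f"no site has {n} records; all rarefied values are missing",
            DroppedDataWarning,
            stacklevel=2,
        )
    return SiteIndexTable(cm.site_ids, values, "RSR", {"n": n, "reps": reps, "seed": seed})


def weighted_endemism(cm: CommunityMatrix) -> SiteIndexTable:
    """WE(site) = Σ over species present of 1 / (species' occupied-site count)."""
    _require_nonempty(cm)
    range_size = cm.incidence.sum(axis=0).astype(float)  # >= 1 after column pruning
    we = cm.incidence @ (1.0 / range_size)
    return SiteIndexTable(cm.site_ids, we, "WE")


def _tree_incidence(species: list, incidence: np.ndarray, tree: Phylogeny) -> np.ndarray:
    try:
        cols = tree.tip_indices(species)
    except KeyError as exc:
        raise ConfigError(str(exc)) from exc
    inc = np.zeros((incidence.shape[0], tree.n_tips), dtype=bool)
    inc[:, cols] = incidence
    return inc


def faith_pd(cm: CommunityMatrix, tree: Phylogeny) -> SiteIndexTable:
    """Rooted Faith PD: branch length of the minimal root-connected subtree."""
    _require_nonempty(cm)
    edges_in = tree.edges_for_incidence(_tree_incidence(cm.species, cm.incidence, tree))
    pd_values = edges_in @ tree.edge_lengths
    return SiteIndexTable(cm.site_ids, pd_values, "PD")


def phylogenetic_endemism(cm: CommunityMatrix, tree: Phylogeny) -> SiteIndexTable:
    """PE: each subtree branch down-weighted by the number of sites holding it."""
    _require_nonempty(cm)
    edges_in = tree.edges_for_incidence(_tree_incidence(cm.species, cm.incidence, tree))
    branch_range = edges_in.sum(axis=0).astype(float)
    weights = np.divide(
        tree.edge_lengths,
        branch_range,
        out=np.zeros_like(tree.edge_lengths),
        where=branch_range > 0,
    )
    pe = edges_in @ weights
    return SiteIndexTable(cm.site_ids, pe, "PE")


def _partition(a, b, c):
    """Sørensen partition from shared (a) and unique (b, c) quantities."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    bc_min = np.minimum(b, c)
    sorensen = (b + c) / (2 * a + b + c)
    simpson = np.divide(
        bc_min, a + bc_min, out=np.zeros_like(bc_min), where=(a + bc_min) > 0
    )
    return sorensen, simpson, sorensen - simpson


def beta_pairwise(site_a: set, site_b: set) -> tuple[float, float, float]:
    """(sorensen, simpson, nestedness) for two species sets."""
    if not site_a or not site_b:
        raise UndefinedStatisticError("beta diversity is undefined for an empty site")
    a = len(site_a & site_b)
    b = len(site_a - site_b)
    c = len(site_b - site_a)
    sor, sim, nes = _partition(a, b, c)
    return float(sor), float(sim), float(nes)


def beta_matrix(
    cm: CommunityMatrix, family: str = "taxonomic", tree: Phylogeny | None = None
) -> BetaPartition:
    """All-pairs beta diversity, taxonomic or phylogenetic (PhyloSor family)."""
    _require_nonempty(cm)
    if family not in ("taxonomic", "phylogenetic"):
        raise ConfigError(f"unknown beta family {family!r}")
    if family == "phylogenetic" and tree is None:
        raise ConfigError("phylogenetic beta diversity requires a tree")
    occupied = cm.incidence.any(axis=1)
    if (~occupied).any():
        warnings.warn(
            f"excluded {int((~occupied).sum())} empty sites from the beta matrix",
            DroppedDataWarning,
            stacklevel=2,
        )
    inc = cm.incidence[occupied]
    ids = cm.site_ids[occupied]
    if inc.shape[0] < 2:
        raise EmptyInputError("need at least two non-empty sites")
    if family == "taxonomic":
        shared = (inc.astype(float)) @ inc.T.astype(float)
        totals = inc.sum(axis=1).astype(float)
        names = ("sorensen", "simpson", "nestedness")
    else:
        edges_in = tree.edges_for_incidence(_tree_incidence(cm.species, inc, tree))
        weighted = edges_in * tree.edge_lengths
        shared = weighted @ edges_in.T
        totals = edges_in @ tree.edge_lengths
        names = ("phylosor", "phylosim", "phylosne")
    b = totals[:, None] - shared
    c = totals[None, :] - shared
    sor, sim, nes = _partition(shared, b, c)
    for m in (sor, sim, nes):
        np.fill_diagonal(m, 0.0)
    sor = 0.5 * (sor + sor.T)
    sim = 0.5 * (sim + sim.T)
    nes = sor - sim
    return BetaPartition(
        DissimilarityMatrix(ids, sor, names[0]),
        DissimilarityMatrix(ids, sim, names[1]),
        DissimilarityMatrix(ids, nes, names[2]),
    )
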