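"""Raster-stack statistics and ordination: correlation, variable clustering,
PCA cube with scenario projection and the equal-share axis-significance
rule, global Moran's I and the raster variogram."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._moran import moran_permutation_test
from .errors import (
    ConfigError,
    DegenerateInputError,
    DroppedDataWarning,
    UndefinedStatisticError,
)
from .io.raster import RasterGrid, RasterStack


def raster_correlation(stack: RasterStack) -> pd.DataFrame:
    """Pairwise Pearson correlation of bands over jointly valid cells.

    Constant bands get NaN rows/columns with a warning.
    """
    if len(stack) < 2:
        raise ConfigError("correlation needs at least 2 bands")
    valid = stack.joint_valid()
    if valid.sum() < 3:
        raise DegenerateInputError("fewer than 3 jointly valid cells")
    X = stack.table(valid)
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        names = [n for n, c in zip(stack.names, constant) if c]
        warnings.warn(f"constant bands excluded from correlation: {names}",
                      DroppedDataWarning, stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, np.where(constant, np.nan, 1.0))
    return pd.DataFrame(corr, index=stack.names, columns=stack.names)


@dataclass
class VariableClusters:
    """Disjoint, exhaustive grouping of band names."""

    groups: list[list[str]]
    threshold: float


def cluster_variables(corr: pd.DataFrame, threshold: float) -> VariableClusters:
    """Single-linkage groups: connected components of the |r| ≥ t graph."""
    if not (0 < threshold < 1):
        raise ConfigError("threshold must be in (0, 1)")
    names = list(corr.index)
    m = np.abs(corr.to_numpy(float))
    n = len(names)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(m[i, j]) and m[i, j] >= threshold:
                parent[find(i)] = find(j)
    comps: dict[int, list[str]] = {}
    for i, name in enumerate(names):
        comps.setdefault(find(i), []).append(name)
    groups = sorted((sorted(g) for g in comps.values()), key=lambda g: g[0])
    return VariableClusters(groups, threshold)


# ---------------------------------------------------------------------------
# PCA cube


@dataclass
class PCAModel:
    """Correlation-matrix PCA over standardized bands.

    Component signs are fixed so each component's largest-magnitude loading
    is positive, for reproducibility.
    """

    band_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # (n_bands, n_components)
    eigenvalues: np.ndarray
    standardized: bool = True

    @property
    def percent_variance(self) -> np.ndarray:
        return 100.0 * self.eigenvalues / self.eigenvalues.sum()


def pca_fit(stack: RasterStack, standardize: bool = True) -> PCAModel:
    """Fit PCA on the stack's jointly valid cells (correlation PCA by default)."""
    if len(stack) < 2:
        raise ConfigError("PCA needs at least 2 bands")
    valid = stack.joint_valid()
    X = stack.table(valid)
    if len(X) <= len(stack):
        raise DegenerateInputError("fewer valid cells than bands")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1) if standardize else np.ones(X.shape[1])
    if standardize and np.any(sds == 0):
        bad = [n for n, s in zip(stack.names, sds) if s == 0]
        raise DegenerateInputError(f"constant bands cannot be standardized: {bad}")
    Z = (X - means) / sds
    cov = Z.T @ Z / (len(Z) - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for c in range(eigvecs.shape[1]):
        j = np.argmax(np.abs(eigvecs[:, c]))
        if eigvecs[j, c] < 0:
            eigvecs[:, c] = -eigvecs[:, c]
    return PCAModel(list(stack.names), means, sds, eigvecs, eigvals, standardize)


def _apply_pca(model: PCAModel, stack: RasterStack, n_components: int | None) -> RasterStack:
    k = n_components or len(model.eigenvalues)
    valid = stack.joint_valid()
    X = stack.table(valid)
    Z = (X - model.means) / model.sds
    scores = Z @ model.loadings[:, :k]
    ref = stack.grids[0]
    bands = []
    for c in range(k):
        arr = np.full(stack.shape, ref.nodata, dtype=np.float32)
        arr[valid] = scores[:, c]
        bands.append(ref.like(arr, name=f"PC{c + 1}"))
    return RasterStack(bands, [b.name for b in bands])


def pca_transform(
    model: PCAModel, stack: RasterStack, n_components: int | None = None
) -> RasterStack:
    """Component-score rasters for the training stack."""
    if list(stack.names) != model.band_names:
        raise ConfigError(
            f"band mismatch: model {model.band_names} vs stack {list(stack.names)}"
        )
    return _apply_pca(model, stack, n_components)


def pca_project(
    model: PCAModel, other: RasterStack, n_components: int | None = None
) -> RasterStack:
    """Score a different scenario with the SAME means, SDs and loadings."""
    if sorted(other.names) != sorted(model.band_names):
        missing = set(model.band_names) - set(other.names)
        extra = set(other.names) - set(model.band_names)
        raise ConfigError(f"band-name mismatch: missing {sorted(missing)}, extra {sorted(extra)}")
    if list(other.names) != model.band_names:
        other = RasterStack([other[n] for n in model.band_names], list(model.band_names))
    return _apply_pca(model, other, n_components)


def pca_axis_significance(model: PCAModel, p: int | None = None) -> dict:
    """Components explaining more variance than the equal-share expectation.

    With ``p`` input variables the chance expectation per axis is 100/p
    percent; components whose percent variance strictly exceeds it are
    retained.  The threshold is reported rounded to two decimals.
    """
    if p is None:
        p = len(model.band_names)
    if p < 1:
        raise ConfigError("p must be >= 1")
    threshold = 100.0 / p
    pct = model.percent_variance
    significant = [int(i + 1) for i, v in enumerate(pct) if v > threshold]
    note = None
    if not significant:
        note = "no component exceeds the equal-share threshold"
    return {
        "threshold_pct": round(threshold, 2),
        "significant": significant,
        "percent_variance": pct.tolist(),
        "note": note,
    }


# ---------------------------------------------------------------------------
# spatial statistics on rasters


def _contiguity_weights(valid: np.ndarray, neighborhood: str) -> np.ndarray:
    if neighborhood == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif neighborhood == "queen":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)]
    else:
        raise ConfigError(f"unknown neighborhood {neighborhood!r}")
    idx = -np.ones(valid.shape, dtype=int)
    cells = np.argwhere(valid)
    idx[valid] = np.arange(len(cells))
    n = len(cells)
    W = np.zeros((n, n))
    nrows, ncols = valid.shape
    for dr, dc in offsets:
        r2 = cells[:, 0] + dr
        c2 = cells[:, 1] + dc
        ok = (r2 >= 0) & (r2 < nrows) & (c2 >= 0) & (c2 < ncols)
        ok[ok] &= valid[r2[ok], c2[ok]]
        W[idx[cells[ok, 0], cells[ok, 1]], idx[r2[ok], c2[ok]]] = 1.0
    return W


def global_moran_raster(
    grid: RasterGrid,
    neighborhood: str = "queen",
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Global Moran's I of a raster under binary contiguity weights."""
    valid = grid.valid
    if valid.sum() < 4:
        raise DegenerateInputError("need at least 4 valid cells")
    z = grid.values[valid].astype(float)
    if z.std() == 0:
        raise UndefinedStatisticError("zero-variance raster")
    W = _contiguity_weights(valid, neighborhood)
    result = moran_permutation_test(z, W, n_perm=n_perm, seed=seed)
    result["z"] = (result["I"] - result["expected"]) / result["perm_sd"]
    result["neighborhood"] = neighborhood
    result["seed"] = seed
    return result


def raster_variogram(
    grid: RasterGrid,
    n_bins: int = 15,
    max_dist: float | None = None,
    max_pairs: int = 200_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Empirical semivariogram of cell values at cell centers.

    Cell pairs are subsampled to ``max_pairs`` for large grids (seeded).
    """
    valid = grid.valid
    if valid.sum() < 2:
        raise DegenerateInputError("variogram needs at least 2 valid cells")
    xs, ys = grid.cell_centers()
    px = xs[valid]
    py = ys[valid]
    z = grid.values[valid].astype(float)
    n = len(z)
    rng = np.random.default_rng(seed)
    n_all = n * (n - 1) // 2
    if n_all <= max_pairs:
        iu = np.triu_indices(n, k=1)
        i, j = iu
    else:
        i = rng.integers(0, n, size=int(max_pairs * 1.2))
        j = rng.integers(0, n, size=int(max_pairs * 1.2))
        keep = i < j
        i, j = i[keep][:max_pairs], j[keep][:max_pairs]
    d = np.hypot(px[i] - px[j], py[i] - py[j])
    if d.max() == 0:
        raise DegenerateInputError("all valid cells coincide")
    if max_dist is None:
        max_dist = d.max() / 2.0
    g2 = 0.5 * (z[i] - z[j]) ** 2
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    which = np.digitize(d, edges) - 1
    ok = (which >= 0) & (which < n_bins) & (d > 0)
    gamma = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = ok & (which == b)
        counts[b] = int(sel.sum())
        if counts[b]:
            gamma[b] = float(g2[sel].mean())
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"lag": centers, "semivariance": gamma, "n_pairs": counts})
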