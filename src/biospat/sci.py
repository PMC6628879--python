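"""Composition interpolation: NMDS of a beta-diversity matrix, spatial
premise testing, interpolation of axis scores to rasters, RGB composites and
unsupervised bioregion classification.

The phylogenetic variant (PCI) is the identical pipeline fed a phylogenetic
beta matrix — there is no separate code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from ._moran import inverse_distance_weights, moran_permutation_test
from .diversity import DissimilarityMatrix
from .errors import (
    ConfigError,
    DegenerateInputError,
    PremiseWarning,
    UndefinedStatisticError,
)
from .interp import (
    SampleSet,
    empirical_variogram,
    fit_variogram,
    nn_interpolate,
    ordinary_krige,
    tps_interpolate,
)
from .io.raster import RasterGrid, RasterStack
from .io.vector import StudyArea
from .tiling import CommunityMatrix


@dataclass
class OrdinationResult:
    """Best-of-restarts NMDS configuration with Kruskal stress-1."""

    site_ids: np.ndarray
    scores: np.ndarray  # (n_sites, k), column-centred
    stress: float
    k: int
    n_restarts: int
    seed: int | None


def kruskal_stress(d: np.ndarray, scores: np.ndarray) -> float:
    """Stress-1 of a configuration against condensed dissimilarities ``d``.

    The monotone regression of configuration distances on the dissimilarities
    is recomputed here, independent of the optimiser that produced the
    configuration.
    """
    dist = pdist(scores)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    dhat = iso.fit_transform(d, dist)
    num = float(((dist - dhat) ** 2).sum())
    den = float((dist**2).sum())
    if den == 0:
        return 1.0
    return float(np.sqrt(num / den))


def nmds(
    d: DissimilarityMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1, best of ``n_restarts``."""
    n = d.n
    if n < k + 1:
        raise ConfigError(f"need at least k+1={k + 1} sites for a {k}-D ordination")
    condensed = d.condensed()
    if np.allclose(condensed, condensed[0]):
        raise DegenerateInputError("all dissimilarities are equal; ordination is degenerate")
    mds = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=seed,
        normalized_stress=True,
        eps=1e-9,
    )
    scores = mds.fit_transform(d.matrix)
    scores = scores - scores.mean(axis=0, keepdims=True)
    stress = kruskal_stress(condensed, scores)
    return OrdinationResult(d.site_ids.copy(), scores, stress, k, n_restarts, seed)


def moran_premise_test(
    result: OrdinationResult,
    coords: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-axis Moran's I of the NMDS scores at the site centers.

    Spatial autocorrelation of the scores is a premise of composition
    interpolation; a :class:`PremiseWarning` is emitted when any axis has
    permutation p > 0.05.  Weights are row-standardised inverse distance.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) != len(result.site_ids):
        raise ConfigError("coords and ordination sites differ in length")
    if len(coords) < 4:
        raise ConfigError("need at least 4 sites for the premise test")
    weights = inverse_distance_weights(coords)
    rows = []
    for axis in range(result.k):
        z = result.scores[:, axis]
        if np.allclose(z, z[0]):
            raise UndefinedStatisticError(f"axis {axis + 1} has zero variance")
        r = moran_permutation_test(z, weights, n_perm=n_perm, seed=seed)
        rows.append(
            {"axis": axis + 1, "I": r["I"], "expected": r["expected"], "p": r["p"]}
        )
    table = pd.DataFrame(rows)
    bad = table[table["p"] > 0.05]
    if len(bad):
        warnings.warn(
            f"spatial-autocorrelation premise violated on axes "
            f"{bad['axis'].tolist()} (p > 0.05); interpolation may be meaningless",
            PremiseWarning,
            stacklevel=2,
        )
    return table


def interpolate_axes(
    result: OrdinationResult,
    cm: CommunityMatrix,
    target: RasterGrid,
    mask: StudyArea | None = None,
    method: str = "nn",
    smoothing: float = 0.0,
) -> RasterStack:
    """Interpolate each ordination axis from hexagon centers to raster cells."""
    if method not in ("nn", "spline", "kriging"):
        raise ConfigError(f"unknown interpolation method {method!r}")
    order = {int(s): i for i, s in enumerate(result.site_ids)}
    keep = [i for i, sid in enumerate(cm.site_ids) if int(sid) in order]
    centers = cm.site_centers()[keep]
    rows = [order[int(cm.site_ids[i])] for i in keep]
    bands = []
    for axis in range(result.k):
        samples = SampleSet(centers[:, 0], centers[:, 1], result.scores[rows, axis])
        if method == "nn":
            band = nn_interpolate(samples, target, mask)
        elif method == "spline":
            band = tps_interpolate(samples, target, mask, smoothing=smoothing)
        else:
            vm = fit_variogram(empirical_variogram(samples))
            band, _ = ordinary_krige(samples, vm, target, mask)
        band.name = f"axis_{axis + 1}"
        bands.append(band)
    return RasterStack(bands, [b.name for b in bands])


def rgb_composite(stack: RasterStack) -> RasterStack:
    """First three bands min–max rescaled to [0, 255] (floor convention)."""
    if len(stack) < 3:
        raise ConfigError(f"RGB composite needs >= 3 bands, got {len(stack)}")
    out = []
    for channel, band in zip("RGB", stack.grids[:3]):
        valid = band.valid
        vals = band.values[valid].astype(float)
        lo, hi = float(vals.min()), float(vals.max())
        if hi == lo:
            raise DegenerateInputError(
                f"band {band.name!r} is constant and cannot be rescaled"
            )
        scaled = np.floor(255.0 * (vals - lo) / (hi - lo))
        arr = np.full(band.values.shape, band.nodata, dtype=np.float32)
        arr[valid] = scaled
        out.append(band.like(arr, name=channel))
    return RasterStack(out, ["R", "G", "B"])


@dataclass
class BioregionMap:
    """Integer class labels 1..k over cells valid in all input bands."""

    labels: RasterGrid
    method: str
    k: int
    seed: int | None


def _pam(data: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 50):
    """Basic PAM (build + swap) on a data subsample; returns medoid indices."""
    n = len(data)
    d = np.linalg.norm(data[:, None, :] - data[None, :, :], axis=-1)
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        assign = np.argmin(d[:, medoids], axis=1)
        changed = False
        for j in range(k):
            members = np.flatnonzero(assign == j)
            if len(members) == 0:
                continue
            costs = d[np.ix_(members, members)].sum(axis=0)
            best = members[np.argmin(costs)]
            if best != medoids[j]:
                medoids[j] = best
                changed = True
        if not changed:
            break
    return medoids


def classify_regions(
    stack: RasterStack,
    k: int,
    method: str = "kmeans",
    n_init: int = 10,
    seed: int | None = None,
    clara_sample: int = 500,
) -> BioregionMap:
    """Cluster cells of a (z-scored) multiband raster into k bioregions.

    ``kmedoids`` is CLARA-style: PAM on a cell subsample, all cells then
    assigned to their nearest medoid; best of ``n_init`` subsamples kept.
    """
    if k < 2:
        raise ConfigError("k must be >= 2")
    if method not in ("kmeans", "kmedoids"):
        raise ConfigError(f"unknown classification method {method!r}")
    valid = stack.joint_valid()
    X = stack.table(valid)
    if len(X) < k:
        raise DegenerateInputError(f"only {len(X)} valid cells for k={k}")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    if len(np.unique(Xz, axis=0)) < k:
        raise DegenerateInputError(f"fewer than k={k} distinct cell vectors")
    rng = np.random.default_rng(seed)
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_init, random_state=rng.integers(2**31 - 1))
        labels = km.fit_predict(Xz)
    else:
        best = None
        for _ in range(n_init):
            sub = rng.choice(len(Xz), size=min(clara_sample, len(Xz)), replace=False)
            medoid_rows = sub[_pam(Xz[sub], k, rng)]
            d = np.linalg.norm(Xz[:, None, :] - Xz[medoid_rows][None, :, :], axis=-1)
            assign = np.argmin(d, axis=1)
            cost = float(d[np.arange(len(Xz)), assign].sum())
            if best is None or cost < best[0]:
                best = (cost, assign)
        labels = best[1]
    ref = stack.grids[0]
    arr = np.full(ref.values.shape, ref.nodata, dtype=np.float32)
    arr[valid] = labels.astype(np.float32) + 1.0
    return BioregionMap(ref.like(arr, name="bioregions"), method, k, seed)
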