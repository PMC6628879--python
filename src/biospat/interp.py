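"""Spatial interpolators and predictor-based surfaces.

Provides nearest-neighbour, thin-plate-spline and ordinary-kriging
interpolation of point samples to rasters, empirical variogram estimation
with weighted-least-squares model fitting, GLM prediction surfaces, and a
quartic-kernel sampling-effort density.  Diversity surfaces are simple
compositions: per-hexagon index values become a :class:`SampleSet` at the
hexagon centers and run through any interpolator here.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import RBFInterpolator
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import (
    ConfigError,
    DegenerateInputError,
    DroppedDataWarning,
    EmptyInputError,
    SchemaError,
)
from .io.occurrences import OccurrenceTable
from .io.raster import RasterGrid
from .io.vector import StudyArea

__all__ = [
    "SampleSet",
    "read_samples",
    "samples_from_site_index",
    "nn_interpolate",
    "tps_interpolate",
    "empirical_variogram",
    "VariogramModel",
    "fit_variogram",
    "ordinary_krige",
    "GLMModel",
    "glm_fit",
    "glm_predict_surface",
    "sampling_effort",
    "masked_target",
]


@dataclass
class SampleSet:
    """Point samples of one dependent variable."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    crs: str | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.values)):
            raise SchemaError("x, y, values must have equal length")
        if len(self.x) == 0:
            raise EmptyInputError("empty sample set")
        if not (
            np.isfinite(self.x).all()
            and np.isfinite(self.y).all()
            and np.isfinite(self.values).all()
        ):
            raise SchemaError("non-finite sample coordinates or values")

    def __len__(self) -> int:
        return len(self.values)

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def read_samples(path: str | os.PathLike, delimiter: str = ",") -> SampleSet:
    """Read a dependent/x/y CSV (case-insensitive, order-free columns)."""
    df = pd.read_csv(path, sep=delimiter, skipinitialspace=True)
    cols = {c.strip().lower(): c for c in df.columns}
    for required in ("dependent", "x", "y"):
        if required not in cols:
            raise SchemaError(f"missing required column {required!r} in {path!r}")
    sub = df[[cols["dependent"], cols["x"], cols["y"]]].apply(pd.to_numeric, errors="coerce")
    ok = sub.notna().all(axis=1)
    if int((~ok).sum()):
        warnings.warn(
            f"dropped {int((~ok).sum())} malformed sample rows", DroppedDataWarning, stacklevel=2
        )
    if ok.sum() == 0:
        raise EmptyInputError(f"no valid sample rows in {path!r}")
    sub = sub[ok]
    return SampleSet(
        sub[cols["x"]].to_numpy(), sub[cols["y"]].to_numpy(), sub[cols["dependent"]].to_numpy()
    )


def samples_from_site_index(table, cm) -> SampleSet:
    """Per-hexagon index values → samples at the hexagon centers (NaN dropped)."""
    centers = cm.site_centers()
    ok = np.isfinite(table.values)
    if not ok.any():
        raise EmptyInputError("site index table has no defined values")
    return SampleSet(centers[ok, 0], centers[ok, 1], table.values[ok])


def masked_target(target: RasterGrid, mask: StudyArea | None) -> np.ndarray:
    """Boolean cell mask: inside the study area (all cells when mask is None)."""
    if mask is None:
        return np.ones(target.values.shape, dtype=bool)
    xs, ys = target.cell_centers()
    return mask.contains_xy(xs.ravel(), ys.ravel()).reshape(target.values.shape)


def _finish(target: RasterGrid, cellmask: np.ndarray, filled: np.ndarray, name=None) -> RasterGrid:
    out = np.full(target.values.shape, target.nodata, dtype=np.float32)
    out[cellmask] = filled
    return target.like(out, name=name)


def nn_interpolate(
    samples: SampleSet, target: RasterGrid, mask: StudyArea | None = None
) -> RasterGrid:
    """Each cell takes the value of its nearest sample (ties → lowest index)."""
    cellmask = masked_target(target, mask)
    xs, ys = target.cell_centers()
    pts = np.column_stack([xs[cellmask], ys[cellmask]])
    tree = cKDTree(samples.coords())
    k = min(4, len(samples))
    dist, idx = tree.query(pts, k=k)
    if k == 1:
        nearest = np.atleast_1d(idx)
    else:
        # deterministic tie-break: smallest sample index among equidistant
        tied = dist <= dist[:, [0]] * (1 + 1e-12) + 1e-300
        masked_idx = np.where(tied, idx, len(samples))
        nearest = masked_idx.min(axis=1)
    return _finish(target, cellmask, samples.values[nearest])


def tps_interpolate(
    samples: SampleSet,
    target: RasterGrid,
    mask: StudyArea | None = None,
    smoothing: float = 0.0,
) -> RasterGrid:
    """Thin-plate spline (r² log r basis + affine part).

    ``smoothing=0`` interpolates the samples exactly; larger values approach
    the least-squares plane.
    """
    if smoothing < 0:
        raise ConfigError("smoothing must be >= 0")
    if len(samples) < 3:
        raise DegenerateInputError("thin-plate spline needs at least 3 samples")
    cellmask = masked_target(target, mask)
    xs, ys = target.cell_centers()
    pts = np.column_stack([xs[cellmask], ys[cellmask]])
    try:
        rbf = RBFInterpolator(
            samples.coords(),
            samples.values,
            kernel="thin_plate_spline",
            smoothing=smoothing,
        )
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(
            "singular thin-plate system (collinear samples?); try smoothing > 0"
        ) from exc
    return _finish(target, cellmask, rbf(pts))


# ---------------------------------------------------------------------------
# variograms and ordinary kriging


def empirical_variogram(
    samples: SampleSet, n_bins: int = 15, max_dist: float | None = None
) -> pd.DataFrame:
    """Binned semivariance γ(h) = mean of ½(zᵢ−zⱼ)² over pairs in each lag bin.

    Returns a frame with columns ``lag``, ``semivariance``, ``n_pairs``;
    empty bins have NaN semivariance.
    """
    if len(samples) < 2:
        raise EmptyInputError("variogram needs at least 2 samples")
    d = pdist(samples.coords())
    if d.max() == 0:
        raise DegenerateInputError("all sample points coincide")
    if max_dist is None:
        max_dist = d.max() / 2.0
    dz2 = 0.5 * pdist(samples.values[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    which = np.digitize(d, edges) - 1
    ok = (which >= 0) & (which < n_bins) & (d > 0)
    gamma = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = ok & (which == b)
        counts[b] = int(sel.sum())
        if counts[b]:
            gamma[b] = float(dz2[sel].mean())
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"lag": centers, "semivariance": gamma, "n_pairs": counts})


@dataclass
class VariogramModel:
    """Parametric semivariance model γ(h); ``range_`` is the practical range."""

    model: str
    nugget: float
    sill: float
    range_: float

    def __post_init__(self):
        if self.model not in ("exponential", "spherical", "gaussian"):
            raise ConfigError(f"unknown variogram model {self.model!r}")
        if self.nugget < 0 or self.sill < self.nugget or self.range_ <= 0:
            raise ConfigError("need 0 <= nugget <= sill and range > 0")

    def semivariance(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        psill = self.sill - self.nugget
        if self.model == "exponential":
            g = psill * (1.0 - np.exp(-3.0 * h / self.range_))
        elif self.model == "gaussian":
            g = psill * (1.0 - np.exp(-3.0 * h**2 / self.range_**2))
        else:  # spherical
            hr = np.clip(h / self.range_, 0.0, 1.0)
            g = psill * (1.5 * hr - 0.5 * hr**3)
        out = self.nugget + g
        return np.where(h == 0, self.nugget, out)

    def covariance(self, h) -> np.ndarray:
        """C(h) = sill − γ(h), with C(0) = sill."""
        h = np.asarray(h, dtype=float)
        return np.where(h == 0, self.sill, self.sill - self.semivariance(h))


def fit_variogram(empirical: pd.DataFrame, model: str = "auto") -> VariogramModel:
    """Weighted least squares (weights = pair counts) fit of a variogram model.

    ``model='auto'`` tries exponential, spherical and gaussian and keeps the
    lowest weighted residual.
    """
    table = empirical.dropna(subset=["semivariance"])
    table = table[table["n_pairs"] > 0]
    if len(table) < 3:
        raise DegenerateInputError("too few non-empty variogram bins to fit")
    h = table["lag"].to_numpy(float)
    g = table["semivariance"].to_numpy(float)
    w = np.sqrt(table["n_pairs"].to_numpy(float))
    names = ("exponential", "spherical", "gaussian") if model == "auto" else (model,)
    sill0 = max(g.max(), 1e-12)
    range0 = max(h.max() * 0.5, 1e-9)
    best = None
    for name in names:
        def resid(p, name=name):
            vm = VariogramModel(name, p[0], p[0] + p[1], p[2])
            return w * (vm.semivariance(h) - g)

        sol = least_squares(
            resid,
            x0=[min(g.min(), sill0 * 0.1), sill0, range0],
            bounds=([0.0, 1e-12, 1e-12], [sill0 * 2, sill0 * 4, h.max() * 4]),
        )
        cost = float(sol.cost)
        if best is None or cost < best[0]:
            best = (cost, name, sol.x)
    _, name, p = best
    return VariogramModel(name, float(p[0]), float(p[0] + p[1]), float(p[2]))


def _dedupe(samples: SampleSet) -> SampleSet:
    coords = samples.coords()
    uniq, inv = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return samples
    vals = np.zeros(len(uniq))
    counts = np.bincount(inv)
    np.add.at(vals, inv, samples.values)
    warnings.warn(
        f"averaged {len(coords) - len(uniq)} duplicate sample locations",
        DroppedDataWarning,
        stacklevel=3,
    )
    return SampleSet(uniq[:, 0], uniq[:, 1], vals / counts, crs=samples.crs)


def ordinary_krige(
    samples: SampleSet,
    vm: VariogramModel,
    target: RasterGrid,
    mask: StudyArea | None = None,
    max_global: int = 2000,
    n_neighbors: int = 64,
) -> tuple[RasterGrid, RasterGrid]:
    """Ordinary kriging prediction and variance surfaces.

    Uses the global system (all samples) up to ``max_global`` samples, else a
    moving neighbourhood of the ``n_neighbors`` nearest samples per cell.
    Exact at sample locations when nugget = 0.
    """
    samples = _dedupe(samples)
    n = len(samples)
    if n < 3:
        raise DegenerateInputError("ordinary kriging needs at least 3 samples")
    cellmask = masked_target(target, mask)
    xs, ys = target.cell_centers()
    pts = np.column_stack([xs[cellmask], ys[cellmask]])
    coords = samples.coords()
    z = samples.values

    def solve_block(sample_idx: np.ndarray, cells: np.ndarray):
        sc = coords[sample_idx]
        m = len(sample_idx)
        A = np.empty((m + 1, m + 1))
        A[:m, :m] = vm.covariance(squareform(pdist(sc)))
        A[m, :m] = 1.0
        A[:m, m] = 1.0
        A[m, m] = 0.0
        B = np.empty((m + 1, len(cells)))
        B[:m] = vm.covariance(cdist(sc, cells))
        B[m] = 1.0
        try:
            lu = lu_factor(A)
            W = lu_solve(lu, B)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise DegenerateInputError(f"singular kriging system: {exc}") from exc
        pred = W[:m].T @ z[sample_idx]
        var = vm.sill - np.einsum("ij,ij->j", W[:m], B[:m]) - W[m]
        return pred, np.maximum(var, 0.0)

    if n <= max_global:
        pred, var = solve_block(np.arange(n), pts)
    else:
        tree = cKDTree(coords)
        k = min(n_neighbors, n)
        _, neigh = tree.query(pts, k=k)
        pred = np.empty(len(pts))
        var = np.empty(len(pts))
        # group cells sharing a neighbourhood to reuse factorisations
        order = np.lexsort(neigh.T)
        sorted_neigh = neigh[order]
        start = 0
        for i in range(1, len(pts) + 1):
            if i == len(pts) or not np.array_equal(sorted_neigh[i], sorted_neigh[start]):
                rows = order[start:i]
                p, v = solve_block(neigh[rows[0]], pts[rows])
                pred[rows] = p
                var[rows] = v
                start = i
    return (
        _finish(target, cellmask, pred, name="prediction"),
        _finish(target, cellmask, var, name="variance"),
    )


# ---------------------------------------------------------------------------
# GLM prediction surfaces

_FAMILIES = {
    "gaussian": sm.families.Gaussian,
    "poisson": sm.families.Poisson,
    "binomial": sm.families.Binomial,
}


@dataclass
class GLMModel:
    """Fitted GLM with canonical link over raster predictor bands."""

    family: str
    band_names: list[str]
    coefficients: np.ndarray  # intercept first
    deviance: float
    null_deviance: float
    n_obs: int
    params: dict = field(default_factory=dict)

    @property
    def deviance_explained(self) -> float:
        """Percent deviance explained, 100·(1 − deviance/null deviance)."""
        if self.null_deviance == 0:
            return 0.0
        return 100.0 * (1.0 - self.deviance / self.null_deviance)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.coefficients[0] + X @ self.coefficients[1:]

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = self.linear_predictor(X)
        if self.family == "gaussian":
            return eta
        if self.family == "poisson":
            return np.exp(eta)
        return 1.0 / (1.0 + np.exp(-eta))


def _design_from_stack(stack, x, y) -> tuple[np.ndarray, np.ndarray]:
    cols = [g.sample(x, y) for g in stack.grids]
    X = np.column_stack(cols)
    ok = np.isfinite(X).all(axis=1)
    return X, ok


def glm_fit(
    samples: SampleSet, predictors=None, family: str = "gaussian", max_iter: int = 100
) -> GLMModel:
    """IRLS fit of dependent ~ predictor bands (canonical link).

    ``predictors=None`` fits an intercept-only model (prediction = the
    family's mean of y everywhere).
    """
    if family not in _FAMILIES:
        raise ConfigError(f"unknown family {family!r}")
    if predictors is None:
        X = np.empty((len(samples), 0))
        ok = np.ones(len(samples), dtype=bool)
        band_names: list[str] = []
    else:
        X, ok = _design_from_stack(predictors, samples.x, samples.y)
        band_names = list(predictors.names)
    if int((~ok).sum()):
        warnings.warn(
            f"dropped {int((~ok).sum())} samples outside valid predictor cells",
            DroppedDataWarning,
            stacklevel=2,
        )
    X, yv = X[ok], samples.values[ok]
    n, p = X.shape
    if n <= p + 1:
        raise DegenerateInputError(f"need more than p+1={p + 1} samples, got {n}")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name bands involved in collinearity via correlation on standardized cols
        sd = X.std(axis=0)
        flagged = [band_names[j] for j in range(p) if sd[j] == 0]
        if not flagged:
            corr = np.corrcoef(X, rowvar=False)
            pairs = np.argwhere(np.triu(np.abs(corr) > 1 - 1e-10, k=1))
            flagged = sorted({band_names[i] for pr in pairs for i in pr})
        raise DegenerateInputError(f"rank-deficient design; collinear bands: {flagged}")
    model = sm.GLM(yv, design, family=_FAMILIES[family]())
    result = model.fit(maxiter=max_iter)
    if not getattr(result, "converged", True):
        raise DegenerateInputError(
            f"IRLS did not converge in {max_iter} iterations; deviance trace: "
            f"{getattr(result, 'fit_history', {}).get('deviance', [])[-5:]}"
        )
    return GLMModel(
        family,
        band_names,
        np.asarray(result.params, dtype=float),
        float(result.deviance),
        float(result.null_deviance),
        n,
        {"max_iter": max_iter},
    )


def glm_predict_surface(
    model: GLMModel, predictors, mask: StudyArea | None = None
) -> RasterGrid:
    """Apply a fitted GLM over the predictor stack inside the mask.

    For an intercept-only model the stack supplies geometry only.
    """
    target = predictors.grids[0]
    if not model.band_names:
        cellmask = masked_target(target, mask)
        X = np.empty((int(cellmask.sum()), 0))
    else:
        if list(predictors.names) != model.band_names:
            raise ConfigError(
                f"band mismatch: model has {model.band_names}, "
                f"stack has {list(predictors.names)}"
            )
        cellmask = masked_target(target, mask) & predictors.joint_valid()
        X = predictors.table(cellmask)
    return _finish(target, cellmask, model.predict(X), name="glm_prediction")


def sampling_effort(
    points: OccurrenceTable,
    target: RasterGrid,
    mask: StudyArea | None = None,
    bandwidth: float = 1.0,
) -> RasterGrid:
    """Quartic kernel density of records, normalised so that
    cell_area · Σ density ≈ number of records (per-record kernels integrate
    to 1; edge losses only where kernels overrun the mask)."""
    if bandwidth <= 0:
        raise ConfigError("bandwidth must be > 0")
    cellmask = masked_target(target, mask)
    xs, ys = target.cell_centers()
    pts = np.column_stack([xs[cellmask], ys[cellmask]])
    density = np.zeros(len(pts))
    tree = cKDTree(pts)
    norm = 3.0 / (np.pi * bandwidth**2)
    for px, py in zip(points.x, points.y):
        hit = tree.query_ball_point([px, py], bandwidth)
        if not hit:
            continue
        hit = np.asarray(hit)
        d = np.hypot(pts[hit, 0] - px, pts[hit, 1] - py)
        u = d / bandwidth
        density[hit] += norm * (1.0 - u**2) ** 2
    return _finish(target, cellmask, density, name="sampling_effort")
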