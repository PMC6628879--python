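"""SDM pre/post-processing: the Bioclim envelope, pseudo-absence generation,
binary-map validation statistics, AUC, niche overlap, convex hulls, sample
points and small raster utilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import shapely.geometry as sgeom
from scipy.spatial import cKDTree

from .errors import (
    ConfigError,
    DegenerateInputError,
    DroppedDataWarning,
    EmptyInputError,
    UndefinedStatisticError,
)
from .interp import sampling_effort
from .io.occurrences import OccurrenceTable
from .io.raster import RasterGrid, RasterStack
from .io.vector import StudyArea


# ---------------------------------------------------------------------------
# Bioclim


def _percentile_rank(sample: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Midpoint-convention percentile rank of ``values`` within ``sample``."""
    sample = np.sort(sample)
    n = len(sample)
    below = np.searchsorted(sample, values, side="left")
    above = np.searchsorted(sample, values, side="right")
    return (below + 0.5 * (above - below)) / n


def bioclim_envelope(presences: OccurrenceTable, predictors: RasterStack) -> RasterGrid:
    """Percentile-envelope suitability in [0, 1].

    Per band, a cell scores 2·min(p, 1−p) where p is the percentile rank of
    the cell's value in the presence sample; the cell's suitability is the
    minimum over bands, and values outside the presence min–max score 0.
    """
    X = np.column_stack([g.sample(presences.x, presences.y) for g in predictors.grids])
    ok = np.isfinite(X).all(axis=1)
    if ok.sum() < 5:
        raise EmptyInputError(
            f"need >= 5 presences on valid predictor cells, got {int(ok.sum())}"
        )
    X = X[ok]
    valid = predictors.joint_valid()
    cells = predictors.table(valid)
    suit = np.ones(len(cells))
    used_any = False
    for j, name in enumerate(predictors.names):
        sample = X[:, j]
        if sample.max() == sample.min():
            warnings.warn(
                f"band {name!r} is constant over presences; skipped",
                DroppedDataWarning,
                stacklevel=2,
            )
            continue
        used_any = True
        p = _percentile_rank(sample, cells[:, j])
        score = 2.0 * np.minimum(p, 1.0 - p)
        score[(cells[:, j] < sample.min()) | (cells[:, j] > sample.max())] = 0.0
        suit = np.minimum(suit, score)
    if not used_any:
        raise DegenerateInputError("every predictor band is constant over the presences")
    ref = predictors.grids[0]
    out = np.full(ref.values.shape, ref.nodata, dtype=np.float32)
    out[valid] = suit
    return ref.like(out, name="bioclim_suitability")


# ---------------------------------------------------------------------------
# pseudo-absences


def _as_occurrences(x, y, label="pseudo_absence", crs=None) -> OccurrenceTable:
    return OccurrenceTable(np.asarray([label] * len(x), dtype=object), x, y, crs=crs)


def pseudo_absences_random(
    presences: OccurrenceTable | None,
    area: StudyArea,
    n: int,
    min_dist: float = 0.0,
    seed: int | None = None,
    max_tries: int = 200,
) -> OccurrenceTable:
    """Uniform points in the area, each at least ``min_dist`` from every presence."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = area.bounds
    ptree = cKDTree(presences.coords()) if presences is not None else None
    out_x: list[float] = []
    out_y: list[float] = []
    for _ in range(max_tries):
        m = max(4 * n, 256)
        cx = rng.uniform(xmin, xmax, m)
        cy = rng.uniform(ymin, ymax, m)
        keep = area.contains_xy(cx, cy)
        if ptree is not None and min_dist > 0:
            d, _ = ptree.query(np.column_stack([cx, cy]))
            keep &= d >= min_dist
        elif ptree is not None:
            d, _ = ptree.query(np.column_stack([cx, cy]))
            keep &= d > 0
        out_x.extend(cx[keep])
        out_y.extend(cy[keep])
        if len(out_x) >= n:
            break
    if len(out_x) < n:
        raise DegenerateInputError(
            f"could only place {len(out_x)} of {n} pseudo-absences after "
            f"{max_tries} rounds (area too constrained by min_dist={min_dist})"
        )
    return _as_occurrences(np.asarray(out_x[:n]), np.asarray(out_y[:n]), crs=area.crs)


def pseudo_absences_evidence(
    all_records: OccurrenceTable,
    presences: OccurrenceTable,
    area: StudyArea,
    target: RasterGrid,
    n: int,
    bandwidth: float,
    min_dist: float = 0.0,
    seed: int | None = None,
) -> OccurrenceTable:
    """Pseudo-absences drawn from the best-sampled regions.

    Candidate cells are weighted by the quartic-kernel sampling-effort
    density of ``all_records``; cells holding (or within ``min_dist`` of) a
    focal presence are ineligible.  ``n`` cells are drawn without
    replacement and each point is jittered uniformly within its cell.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    effort = sampling_effort(all_records, target, area, bandwidth)
    valid = effort.valid
    xs, ys = effort.cell_centers()
    density = effort.values.astype(float)
    eligible = valid & (density > 0)
    ptree = cKDTree(presences.coords())
    d, _ = ptree.query(np.column_stack([xs.ravel(), ys.ravel()]))
    d = d.reshape(xs.shape)
    halfdiag = 0.5 * np.hypot(effort.transform.dx, effort.transform.dy)
    eligible &= d > max(min_dist, halfdiag)
    idx = np.flatnonzero(eligible.ravel())
    if idx.size == 0:
        raise DegenerateInputError(
            "no eligible cells: sampling density is zero outside the presence buffer"
        )
    weights = density.ravel()[idx]
    weights = weights / weights.sum()
    k = min(n, idx.size)
    if k < n:
        warnings.warn(
            f"only {k} eligible cells for {n} pseudo-absences", DroppedDataWarning, stacklevel=2
        )
    chosen = rng.choice(idx, size=k, replace=False, p=weights)
    rows, cols = np.unravel_index(chosen, xs.shape)
    jx = rng.uniform(-0.5, 0.5, k) * effort.transform.dx
    jy = rng.uniform(-0.5, 0.5, k) * abs(effort.transform.dy)
    return _as_occurrences(xs[rows, cols] + jx, ys[rows, cols] + jy, crs=area.crs)


# ---------------------------------------------------------------------------
# validation statistics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ConfigError("confusion counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn < 1:
            raise ConfigError("confusion counts sum to zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def confusion_statistics(c: ConfusionCounts) -> dict:
    """accuracy/precision/sensitivity/specificity/kappa/TSS from counts.

    Statistics with a zero denominator are reported as None, never 0.
    """
    n = c.total
    accuracy = (c.tp + c.tn) / n
    precision = _safe_div(c.tp, c.tp + c.fp)
    sensitivity = _safe_div(c.tp, c.tp + c.fn)
    specificity = _safe_div(c.tn, c.tn + c.fp)
    tss = (
        sensitivity + specificity - 1.0
        if sensitivity is not None and specificity is not None
        else None
    )
    p_e = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / (n * n)
    kappa = _safe_div(accuracy - p_e, 1.0 - p_e)
    return {
        "tp": c.tp,
        "fp": c.fp,
        "fn": c.fn,
        "tn": c.tn,
        "accuracy": accuracy,
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "kappa": kappa,
        "tss": tss,
    }


def validate_binary(
    obs_xy: np.ndarray, obs_labels: np.ndarray, pred: RasterGrid
) -> dict:
    """Compare labelled points {0,1} with a binary prediction raster.

    Points off the valid raster are dropped and counted in ``n_dropped``.
    """
    obs_xy = np.asarray(obs_xy, dtype=float)
    labels = np.asarray(obs_labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ConfigError("observation labels must be 0/1")
    values = pred.sample(obs_xy[:, 0], obs_xy[:, 1])
    ok = np.isfinite(values)
    n_dropped = int((~ok).sum())
    if ok.sum() == 0:
        raise EmptyInputError("no observation falls on a valid prediction cell")
    v = values[ok]
    uniq = set(np.unique(v))
    if uniq - {0.0, 1.0}:
        raise ConfigError(f"prediction raster is not binary: values {sorted(uniq)[:5]}")
    pl = v.astype(int)
    ol = labels[ok]
    counts = ConfusionCounts(
        tp=int(((ol == 1) & (pl == 1)).sum()),
        fp=int(((ol == 0) & (pl == 1)).sum()),
        fn=int(((ol == 1) & (pl == 0)).sum()),
        tn=int(((ol == 0) & (pl == 0)).sum()),
    )
    stats = confusion_statistics(counts)
    stats["n_dropped"] = n_dropped
    return stats


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann–Whitney AUC: (concordant + ½·tied) / (n₊·n₋)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedStatisticError("AUC needs at least one positive and one negative")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def auc_from_raster(
    obs_xy: np.ndarray, obs_labels: np.ndarray, score: RasterGrid
) -> float:
    """AUC of raster scores sampled at labelled points (invalid cells dropped)."""
    obs_xy = np.asarray(obs_xy, dtype=float)
    values = score.sample(obs_xy[:, 0], obs_xy[:, 1])
    ok = np.isfinite(values)
    if int((~ok).sum()):
        warnings.warn(
            f"dropped {int((~ok).sum())} points off the score raster",
            DroppedDataWarning,
            stacklevel=2,
        )
    return auc(np.asarray(obs_labels)[ok], values[ok])


# ---------------------------------------------------------------------------
# niche overlap, hulls, sample points, raster utilities


def niche_overlap(sa: RasterGrid, sb: RasterGrid) -> tuple[float, float]:
    """Schoener's D and Hellinger-based I over jointly valid cells."""
    if not sa.aligned_with(sb):
        raise ConfigError("suitability rasters are not aligned")
    joint = sa.valid & sb.valid
    pa = sa.values[joint].astype(float)
    pb = sb.values[joint].astype(float)
    if pa.sum() <= 0 or pb.sum() <= 0:
        raise DegenerateInputError("zero-sum suitability raster cannot be normalised")
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    d = 1.0 - 0.5 * np.abs(pa - pb).sum()
    i = 1.0 - 0.5 * ((np.sqrt(pa) - np.sqrt(pb)) ** 2).sum()
    return float(d), float(i)


def minimum_convex_hull(occ: OccurrenceTable, species: str | None = None):
    """Convex hull polygon of a species' records; area in crs units²."""
    table = occ.subset(species) if species is not None else occ
    pts = sgeom.MultiPoint(table.coords())
    hull = pts.convex_hull
    if hull.geom_type != "Polygon":
        raise DegenerateInputError(
            f"records are degenerate (collinear or < 3 points): hull is {hull.geom_type}"
        )
    return hull


def create_sample_points(
    source: RasterGrid | StudyArea, n: int, species: str = "sample"
) -> OccurrenceTable:
    """Regular lattice of exactly ``n`` points inside a binary map or polygon.

    The lattice pitch is tuned so the clipped count lands as close to ``n``
    as possible; surplus points are dropped from the lattice tail.  Sources
    too small for even one lattice node fall back to a single centroid.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if isinstance(source, RasterGrid):
        valid = source.valid
        uniq = np.unique(source.values[valid])
        if set(uniq) - {0.0, 1.0}:
            raise ConfigError("source raster is not binary")
        xs, ys = source.cell_centers()
        inside_fn = lambda px, py: np.isfinite(source.sample(px, py)) & (
            source.sample(px, py) == 1.0
        )
        mask_presence = valid & (source.values == 1.0)
        if not mask_presence.any():
            raise EmptyInputError("binary map has no presence cells")
        xmin, xmax = xs[mask_presence].min(), xs[mask_presence].max()
        ymin, ymax = ys[mask_presence].min(), ys[mask_presence].max()
        area_est = mask_presence.sum() * source.cell_area
    else:
        geom = source.geometry
        xmin, ymin, xmax, ymax = geom.bounds
        inside_fn = lambda px, py: shapely.intersects_xy(geom, px, py)
        area_est = geom.area

    def lattice(pitch):
        gx = np.arange(xmin + pitch / 2, xmax + pitch / 2, pitch)
        gy = np.arange(ymin + pitch / 2, ymax + pitch / 2, pitch)
        if len(gx) == 0 or len(gy) == 0:
            return np.empty((0, 2))
        mx, my = np.meshgrid(gx, gy)
        pts = np.column_stack([mx.ravel(), my.ravel()])
        keep = inside_fn(pts[:, 0], pts[:, 1])
        return pts[keep]

    pitch = float(np.sqrt(max(area_est, 1e-300) / n))
    best = lattice(pitch)
    # bisect pitch until the clipped lattice holds at least n points
    lo, hi = pitch / 64, pitch * 4
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        pts = lattice(mid)
        if len(pts) >= n:
            best = pts
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-6:
            break
    if len(best) < n:
        if len(best) == 0:
            warnings.warn(
                "source smaller than one lattice node; falling back to centroid",
                DroppedDataWarning,
                stacklevel=2,
            )
            if isinstance(source, RasterGrid):
                xs, ys = source.cell_centers()
                m = source.valid & (source.values == 1.0)
                best = np.array([[xs[m].mean(), ys[m].mean()]])
            else:
                c = source.geometry.centroid
                best = np.array([[c.x, c.y]])
        else:
            warnings.warn(
                f"source holds only {len(best)} lattice nodes for n={n}",
                DroppedDataWarning,
                stacklevel=2,
            )
    pts = best[:n]
    return _as_occurrences(pts[:, 0], pts[:, 1], label=species)


def extract_values_to_points(
    occ: OccurrenceTable, stack: RasterStack
) -> pd.DataFrame:
    """Band values sampled at each point (cell-center containment); off-grid
    points get NaN rows."""
    data = {"sp": occ.species, "x": occ.x, "y": occ.y}
    for name, g in zip(stack.names, stack.grids):
        data[name] = g.sample(occ.x, occ.y)
    return pd.DataFrame(data)


def sum_of_maps(stack: RasterStack, require_all: bool = False) -> RasterGrid:
    """Cell-wise sum over bands, ignoring nodata (unless ``require_all``)."""
    valid = stack.joint_valid() if require_all else stack.any_valid()
    total = np.zeros(stack.shape)
    for g in stack.grids:
        v = g.valid
        total[v] += g.values[v].astype(float)
    ref = stack.grids[0]
    out = np.full(stack.shape, ref.nodata, dtype=np.float32)
    out[valid] = total[valid]
    return ref.like(out, name="sum_of_maps")


def area_of_distribution(grid: RasterGrid) -> float:
    """Presence-cell count × cell area of a binary map."""
    valid = grid.valid
    uniq = np.unique(grid.values[valid])
    if set(uniq) - {0.0, 1.0}:
        raise ConfigError("raster is not binary")
    return float((grid.values[valid] == 1.0).sum() * grid.cell_area)


def rescale01(grid: RasterGrid) -> RasterGrid:
    """Min–max rescale of valid cells to [0, 1]."""
    valid = grid.valid
    vals = grid.values[valid].astype(float)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise DegenerateInputError("constant raster cannot be rescaled")
    out = np.full(grid.values.shape, grid.nodata, dtype=np.float32)
    out[valid] = (vals - lo) / (hi - lo)
    return grid.like(out, name="rescaled")
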