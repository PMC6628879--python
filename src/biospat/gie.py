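"""Geographic Interpolation of Endemism: kernel-density delimitation of
areas of endemism (AoE) from congruent restricted-range species.

Per scale (kernel radius R): every species whose maximum centroid-to-record
distance r_s is at most R contributes a quartic (biweight) kernel centred on
its record centroid, weighted by w_s = 1 − r_s/R, so tighter ranges weigh
more.  The consensus surface averages per-scale surfaces after rescaling
each to [0, 1].  AoEs are threshold-connected components supported by at
least two species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely.geometry as sgeom
from scipy import ndimage
from shapely.ops import unary_union

from .errors import ConfigError, DegenerateInputError, DroppedDataWarning
from .io.occurrences import OccurrenceTable
from .io.raster import RasterGrid
from .io.vector import StudyArea, write_polygons_geojson
from .interp import masked_target


@dataclass
class SpeciesRangeSummary:
    """Per-species record centroid and maximum centroid-to-record distance."""

    species: list
    centroids: np.ndarray  # (n_species, 2)
    max_radius: np.ndarray  # r_s >= 0
    n_records: np.ndarray

    def radius_of(self, name: str) -> float:
        return float(self.max_radius[self.species.index(name)])


@dataclass
class AoESurface:
    """Summed weighted kernels at one scale radius."""

    support: RasterGrid
    radius: float
    contributing: list  # species with r_s <= R
    excluded: list  # species with r_s > R at this scale


@dataclass
class AoETable:
    """Extracted areas of endemism with their supporting species."""

    records: list = field(default_factory=list)  # dicts: id, polygon, species, peak

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "aoe_id": r["id"],
                    "n_species": len(r["species"]),
                    "species": ";".join(sorted(r["species"])),
                    "peak_support": r["peak"],
                }
                for r in self.records
            ]
        )

    def to_geojson(self, path) -> None:
        write_polygons_geojson(
            path,
            [r["polygon"] for r in self.records],
            [
                {"aoe_id": r["id"], "n_species": len(r["species"])}
                for r in self.records
            ],
        )


def species_range_summary(occ: OccurrenceTable) -> SpeciesRangeSummary:
    """Arithmetic centroid and max centroid-to-record distance per species."""
    names = occ.species_names
    cents = np.empty((len(names), 2))
    radii = np.empty(len(names))
    counts = np.empty(len(names), dtype=int)
    for i, name in enumerate(names):
        m = occ.species == name
        pts = np.column_stack([occ.x[m], occ.y[m]])
        c = pts.mean(axis=0)
        cents[i] = c
        radii[i] = float(np.hypot(*(pts - c).T).max())
        counts[i] = int(m.sum())
    return SpeciesRangeSummary(list(names), cents, radii, counts)


def default_scales(summary: SpeciesRangeSummary, n_scales: int = 5) -> np.ndarray:
    """Geometric series of radii from the 10th to 90th percentile of r_s > 0."""
    r = summary.max_radius[summary.max_radius > 0]
    if r.size == 0:
        raise DegenerateInputError("every species has a zero range radius")
    lo, hi = np.percentile(r, [10, 90])
    lo = max(lo, 1e-9)
    hi = max(hi, lo * (1 + 1e-9))
    return np.geomspace(lo, hi, n_scales)


def gie_scale(
    summary: SpeciesRangeSummary,
    radius: float,
    target: RasterGrid,
    mask: StudyArea | None = None,
) -> AoESurface:
    """Weighted quartic-kernel surface at one scale radius."""
    if radius <= 0:
        raise ConfigError("kernel radius must be > 0")
    qualify = summary.max_radius <= radius
    contributing = [s for s, q in zip(summary.species, qualify) if q]
    excluded = [s for s, q in zip(summary.species, qualify) if not q]
    cellmask = masked_target(target, mask)
    xs, ys = target.cell_centers()
    support = np.zeros(target.values.shape)
    if not contributing:
        warnings.warn(
            f"no species qualifies at scale R={radius}; surface is zero",
            DroppedDataWarning,
            stacklevel=2,
        )
    for i in np.flatnonzero(qualify):
        w = 1.0 - summary.max_radius[i] / radius
        d = np.hypot(xs - summary.centroids[i, 0], ys - summary.centroids[i, 1])
        u = d / radius
        inside = u <= 1.0
        support[inside] += w * (1.0 - u[inside] ** 2) ** 2
    out = np.full(target.values.shape, target.nodata, dtype=np.float32)
    out[cellmask] = support[cellmask]
    return AoESurface(target.like(out, name=f"gie_R{radius:g}"), radius, contributing, excluded)


def gie_consensus(surfaces: list[AoESurface]) -> RasterGrid:
    """Cell-wise mean of per-scale surfaces, each rescaled to [0,1] by its max.

    Zero surfaces are skipped with a warning; all-zero input is an error.
    """
    if len(surfaces) < 2:
        raise ConfigError("consensus needs at least 2 scales")
    ref = surfaces[0].support
    layers = []
    for s in surfaces:
        if not s.support.aligned_with(ref):
            raise ConfigError("consensus surfaces must share the target grid")
        vals = s.support.filled(np.nan)
        peak = np.nanmax(vals)
        if not np.isfinite(peak) or peak <= 0:
            warnings.warn(
                f"scale R={s.radius} has a zero surface; skipped in consensus",
                DroppedDataWarning,
                stacklevel=2,
            )
            continue
        layers.append(vals / peak)
    if not layers:
        raise DegenerateInputError("all scales have zero surfaces")
    mean = np.nanmean(np.stack(layers), axis=0)
    out = np.where(np.isfinite(mean), mean, ref.nodata).astype(np.float32)
    return ref.like(out, name="gie_consensus")


def extract_aoes(
    surface: RasterGrid,
    summary: SpeciesRangeSummary,
    radius: float,
    threshold: float = 0.5,
) -> AoETable:
    """Connected components (8-connectivity) of support ≥ threshold·max.

    A species belongs to an AoE when its kernel disk (centroid, ``radius``)
    reaches the component; components with fewer than 2 species are
    discarded (endemism requires congruence).
    """
    if not (0 < threshold < 1):
        raise ConfigError("threshold must be in (0, 1)")
    vals = surface.filled(0.0)
    peak = float(vals.max())
    table = AoETable()
    if peak <= 0:
        return table
    binary = vals >= threshold * peak
    labels, n_comp = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n_comp == 0:
        return table
    xs, ys = surface.cell_centers()
    dx = surface.transform.dx
    dy = abs(surface.transform.dy)
    next_id = 1
    for comp in range(1, n_comp + 1):
        inside = labels == comp
        cx, cy = xs[inside], ys[inside]
        members = []
        for i, name in enumerate(summary.species):
            if summary.max_radius[i] > radius:
                continue  # widespread at this scale, never a member
            d2 = (cx - summary.centroids[i, 0]) ** 2 + (cy - summary.centroids[i, 1]) ** 2
            if d2.min() <= radius**2:
                members.append(name)
        if len(members) < 2:
            continue
        cells = [
            sgeom.box(x - dx / 2, y - dy / 2, x + dx / 2, y + dy / 2)
            for x, y in zip(cx, cy)
        ]
        polygon = unary_union(cells)
        table.records.append(
            {
                "id": next_id,
                "polygon": polygon,
                "species": members,
                "peak": float(vals[inside].max()),
            }
        )
        next_id += 1
    return table
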