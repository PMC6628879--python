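"""Equal-area hexagonal sample units and site × species incidence matrices.

Hexagons are flat-topped with side (edge) length ``s``, so every cell has
area (3√3/2)·s².  The lattice is anchored at the study-area bounding-box
lower-left corner, which makes gridding translation-consistent: shifting the
mask and all points by the same vector yields the same community matrix up
to cell relabelling.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

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
)
from .io.occurrences import OccurrenceTable
from .io.raster import RasterStack
from .io.vector import StudyArea, write_polygons_geojson

SQRT3 = math.sqrt(3.0)

_HEX_ANGLES = np.deg2rad(np.arange(0, 360, 60))
_HEX_UNIT = np.column_stack([np.cos(_HEX_ANGLES), np.sin(_HEX_ANGLES)])


def hexagon_area(side: float) -> float:
    return 1.5 * SQRT3 * side * side


@dataclass
class HexGrid:
    """Flat-topped hexagon lattice clipped to a study area."""

    cell_ids: np.ndarray  # int, 0..n-1
    centers: np.ndarray  # (n, 2)
    side: float
    crs: str | None = None
    _polygons: list = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.cell_ids)

    @property
    def polygons(self) -> list:
        if self._polygons is None:
            self._polygons = [
                sgeom.Polygon(c + self.side * _HEX_UNIT) for c in self.centers
            ]
        return self._polygons

    @property
    def cell_area(self) -> float:
        return hexagon_area(self.side)

    def assign(self, x, y) -> np.ndarray:
        """Index (into this grid's cells) of the hexagon containing each point.

        Returns -1 for points outside every retained cell.  A point exactly on
        a shared edge or vertex goes to the covering cell with the smallest
        cell_id.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        pts = np.column_stack([x, y])
        k = min(3, len(self.centers))
        tree = cKDTree(self.centers)
        dist, idx = tree.query(pts, k=k)
        if k == 1:
            dist = dist[:, None]
            idx = idx[:, None]
        poly_arr = np.asarray(self.polygons, dtype=object)
        pt_geoms = shapely.points(pts)
        big = len(self.centers)
        candidate = np.full((len(pts), k), big, dtype=int)
        for c in range(k):
            # only centers within the circumradius can contain the point
            near = dist[:, c] <= self.side * (1 + 1e-12)
            cells = idx[near, c]
            hit = shapely.covers(poly_arr[cells], pt_geoms[near])
            rows = np.flatnonzero(near)[hit]
            candidate[rows, c] = idx[rows, c]
        out = candidate.min(axis=1)
        out[out == big] = -1
        return out

    def to_geojson(self, path: str | os.PathLike) -> None:
        props = [{"cell_id": int(cid)} for cid in self.cell_ids]
        write_polygons_geojson(path, self.polygons, props)


def build_hex_grid(area: StudyArea, side: float) -> HexGrid:
    """Tile the study area with flat-topped hexagons of edge length ``side``.

    Cells are retained when they intersect the mask at all.
    """
    if side <= 0:
        raise ConfigError("hexagon side must be positive")
    xmin, ymin, xmax, ymax = area.bounds
    w, h = xmax - xmin, ymax - ymin
    if side >= max(w, h):
        raise DegenerateInputError(
            f"hexagon side {side} is not smaller than the study-area extent {max(w, h)}"
        )
    # column pitch 1.5s, row pitch √3·s, odd columns shifted up by √3/2·s
    ncol = int(math.ceil(w / (1.5 * side))) + 2
    nrow = int(math.ceil(h / (SQRT3 * side))) + 2
    centers = []
    for i in range(-1, ncol):
        cx = xmin + i * 1.5 * side
        yoff = 0.5 * SQRT3 * side if (i % 2 != 0) else 0.0
        for j in range(-1, nrow):
            centers.append((cx, ymin + j * SQRT3 * side + yoff))
    centers = np.asarray(centers)
    keep = []
    geom = area.geometry
    for c in centers:
        hexagon = sgeom.Polygon(c + side * _HEX_UNIT)
        if hexagon.intersects(geom):
            keep.append(c)
    if not keep:
        raise DegenerateInputError("no hexagon intersects the study area")
    kept = np.asarray(keep)
    order = np.lexsort((kept[:, 1], kept[:, 0]))
    kept = kept[order]
    return HexGrid(np.arange(len(kept)), kept, side, crs=area.crs)


@dataclass
class CommunityMatrix:
    """Sites (hexagon cells) × species incidence with record counts."""

    site_ids: np.ndarray
    species: list
    incidence: np.ndarray  # (n_sites, n_species) bool
    n_records: np.ndarray  # (n_sites, n_species) int
    grid: HexGrid | None = None
    n_dropped_points: int = 0

    def __post_init__(self):
        self.incidence = np.asarray(self.incidence, dtype=bool)
        self.n_records = np.asarray(self.n_records, dtype=int)
        if not np.array_equal(self.incidence, self.n_records >= 1):
            raise ConfigError("incidence must equal (n_records >= 1)")
        empty_species = ~self.incidence.any(axis=0)
        if empty_species.any():
            dropped = [s for s, e in zip(self.species, empty_species) if e]
            warnings.warn(
                f"dropped {len(dropped)} species absent from every site: {dropped[:5]}",
                DroppedDataWarning,
                stacklevel=2,
            )
            keep = ~empty_species
            self.species = [s for s, k in zip(self.species, keep) if k]
            self.incidence = self.incidence[:, keep]
            self.n_records = self.n_records[:, keep]

    @property
    def n_sites(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_species(self) -> int:
        return self.incidence.shape[1]

    def site_centers(self) -> np.ndarray:
        if self.grid is None:
            raise ConfigError("community matrix has no geometry link")
        pos = {int(cid): i for i, cid in enumerate(self.grid.cell_ids)}
        rows = [pos[int(s)] for s in self.site_ids]
        return self.grid.centers[rows]

    def species_sets(self) -> list[set]:
        return [
            {self.species[j] for j in np.flatnonzero(self.incidence[i])}
            for i in range(self.n_sites)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.incidence.astype(int), index=self.site_ids, columns=self.species
        ).rename_axis("cell_id")

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path)


def assign_points(occ: OccurrenceTable, grid: HexGrid) -> CommunityMatrix:
    """Map occurrence records to hexagons; points outside all cells dropped."""
    cell_of = grid.assign(occ.x, occ.y)
    inside = cell_of >= 0
    n_dropped = int((~inside).sum())
    if inside.sum() == 0:
        raise EmptyInputError("no occurrence point falls inside the hexagon grid")
    if n_dropped:
        warnings.warn(
            f"{n_dropped} points outside the study area were ignored",
            DroppedDataWarning,
            stacklevel=2,
        )
    species = list(pd.unique(occ.species[inside]))
    sp_index = {s: j for j, s in enumerate(species)}
    occupied = np.unique(cell_of[inside])
    site_pos = {int(c): i for i, c in enumerate(occupied)}
    counts = np.zeros((len(occupied), len(species)), dtype=int)
    for cell, sp in zip(cell_of[inside], occ.species[inside]):
        counts[site_pos[int(cell)], sp_index[sp]] += 1
    site_ids = grid.cell_ids[occupied]
    return CommunityMatrix(
        site_ids, species, counts >= 1, counts, grid=grid, n_dropped_points=n_dropped
    )


def community_from_binary_stack(
    stack: RasterStack, grid: HexGrid, rule: str = "any"
) -> CommunityMatrix:
    """Presence per hexagon from per-species binary maps.

    ``rule='any'``: a species is present in a cell when at least one presence
    pixel falls in it; ``rule='majority'``: when more than half of the cell's
    valid pixels are presence.
    """
    if rule not in ("any", "majority"):
        raise ConfigError(f"unknown rule {rule!r}")
    ref = stack.grids[0]
    xs, ys = ref.cell_centers()
    cell_of = grid.assign(xs.ravel(), ys.ravel())
    n_cells = len(grid)
    species, presence_rows = [], []
    for name, band in zip(stack.names, stack.grids):
        vals = band.values
        valid = band.valid
        uniq = np.unique(vals[valid])
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ConfigError(f"band {name!r} is not binary (values {uniq[:5]})")
        flat_valid = valid.ravel() & (cell_of >= 0)
        flat_pres = flat_valid & (vals.ravel() == 1.0)
        n_valid = np.bincount(cell_of[flat_valid], minlength=n_cells)
        n_pres = np.bincount(cell_of[flat_pres], minlength=n_cells)
        if rule == "any":
            present = n_pres >= 1
        else:
            present = (n_valid > 0) & (n_pres > 0.5 * n_valid)
        species.append(name)
        presence_rows.append(present)
    presence = np.column_stack(presence_rows)
    occupied = np.flatnonzero(presence.any(axis=1))
    if len(occupied) == 0:
        raise EmptyInputError("no species present in any hexagon")
    presence = presence[occupied]
    return CommunityMatrix(
        grid.cell_ids[occupied],
        species,
        presence,
        presence.astype(int),
        grid=grid,
    )
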