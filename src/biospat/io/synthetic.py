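"""Synthetic landscapes with planted biotas.

Generates an occurrence table, phylogeny, environmental raster stack and
study-area mask with a known ground truth, so every downstream analysis can
be tested for recovery of planted structure without external data.

Layout: ``n_regions`` square blocks of side ``block_size`` placed side by
side along the x axis.  Each region owns ``n_species_per_region`` endemic
species whose points are drawn uniformly in a disk of radius
``range_radius`` around a region-interior center, so endemic points never
leave their block.  Shared species are drawn uniformly over the whole area.
The phylogeny groups each region's endemics into a clade (unit branch
lengths); shared species attach at the root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely.geometry as sgeom

from ..errors import ConfigError, DroppedDataWarning
from .occurrences import OccurrenceTable
from .raster import GridTransform, RasterGrid, RasterStack
from .trees import Phylogeny, tree_from_newick
from .vector import StudyArea


@dataclass(frozen=True)
class SyntheticLandscapeConfig:
    n_regions: int = 2
    n_species_per_region: int = 5
    n_shared_species: int = 0
    range_radius: float = 5.0
    n_points_per_species: int = 30
    env_gradients: int = 3
    noise_sd: float = 0.0
    seed: int = 0
    #: side of each square region block; default 10 × range_radius
    block_size: float | None = None
    #: env raster cell size; default block_size / 25
    resolution: float | None = None
    #: if set, species centers are drawn within this distance of the block
    #: center (congruent ranges, for endemism tests); default: uniform over
    #: the block interior
    center_jitter: float | None = None

    def __post_init__(self):
        for name in ("n_regions", "n_species_per_region", "n_points_per_species", "env_gradients"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_shared_species < 0:
            raise ConfigError("n_shared_species must be >= 0")
        if self.range_radius <= 0:
            raise ConfigError("range_radius must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        block = self.block_size if self.block_size is not None else 10.0 * self.range_radius
        inset = self.range_radius + (self.center_jitter or 0.0)
        if block / 2.0 <= inset:
            raise ConfigError(
                f"region blocks of side {block} are too small for range_radius "
                f"{self.range_radius} (need side > {2 * inset})"
            )

    @property
    def block(self) -> float:
        return self.block_size if self.block_size is not None else 10.0 * self.range_radius

    @property
    def res(self) -> float:
        return self.resolution if self.resolution is not None else self.block / 25.0


@dataclass
class SyntheticTruth:
    """Planted assignments of the generator."""

    region_raster: RasterGrid  # cell → region id 1..n_regions
    species_region: dict[str, int]  # endemic → region id; shared → 0
    species_centers: dict[str, tuple[float, float]]
    region_bounds: list[tuple[float, float, float, float]]

    def region_of_points(self, x, y) -> np.ndarray:
        vals = self.region_raster.sample(x, y)
        return vals.astype(int)


def _clade(labels: list[str]) -> str:
    if len(labels) == 1:
        return f"{labels[0]}:1"
    mid = len(labels) // 2
    return f"({_clade(labels[:mid])},{_clade(labels[mid:])}):1"


def generate_synthetic_landscape(
    config: SyntheticLandscapeConfig,
) -> tuple[OccurrenceTable, Phylogeny, RasterStack, StudyArea, SyntheticTruth]:
    """Build a fully deterministic landscape; identical seed → identical output."""
    rng = np.random.default_rng(config.seed)
    B = config.block
    n = config.n_regions
    width, height = n * B, B
    area = StudyArea(sgeom.box(0.0, 0.0, width, height))
    region_bounds = [(i * B, 0.0, (i + 1) * B, B) for i in range(n)]

    species: list[str] = []
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    species_region: dict[str, int] = {}
    species_centers: dict[str, tuple[float, float]] = {}

    rho = config.range_radius
    for r in range(n):
        x0, y0, x1, y1 = region_bounds[r]
        cx0, cy0 = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        for s in range(config.n_species_per_region):
            name = f"r{r + 1}_sp{s + 1}"
            if config.center_jitter is not None:
                ang = rng.uniform(0, 2 * np.pi)
                rad = config.center_jitter * np.sqrt(rng.uniform())
                cx, cy = cx0 + rad * np.cos(ang), cy0 + rad * np.sin(ang)
            else:
                cx = rng.uniform(x0 + rho, x1 - rho)
                cy = rng.uniform(y0 + rho, y1 - rho)
            theta = rng.uniform(0, 2 * np.pi, config.n_points_per_species)
            rad = rho * np.sqrt(rng.uniform(size=config.n_points_per_species))
            px = cx + rad * np.cos(theta)
            py = cy + rad * np.sin(theta)
            species.extend([name] * config.n_points_per_species)
            xs.append(px)
            ys.append(py)
            species_region[name] = r + 1
            species_centers[name] = (float(cx), float(cy))
    for s in range(config.n_shared_species):
        name = f"shared_sp{s + 1}"
        px = rng.uniform(0.0, width, config.n_points_per_species)
        py = rng.uniform(0.0, height, config.n_points_per_species)
        species.extend([name] * config.n_points_per_species)
        xs.append(px)
        ys.append(py)
        species_region[name] = 0
        species_centers[name] = (float(px.mean()), float(py.mean()))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DroppedDataWarning)
        occ = OccurrenceTable(
            np.asarray(species, dtype=object), np.concatenate(xs), np.concatenate(ys)
        )

    # phylogeny: one clade per region, shared species at the root
    parts = []
    for r in range(n):
        labels = [f"r{r + 1}_sp{s + 1}" for s in range(config.n_species_per_region)]
        parts.append(_clade(labels))
    parts += [f"shared_sp{s + 1}:1" for s in range(config.n_shared_species)]
    if len(parts) == 1:
        newick = f"({parts[0]});"
    else:
        newick = f"({','.join(parts)});"
    tree = tree_from_newick(newick)

    # environmental bands: smooth gradients of x (region-aligned), y, and
    # harmonics of x, each plus optional white noise
    res = config.res
    ncols = int(round(width / res))
    nrows = int(round(height / res))
    tr = GridTransform(0.0, height, res, -res)
    rows, cols = np.mgrid[0:nrows, 0:ncols]
    cx, cy = tr.cell_center(rows, cols)
    bands = []
    names = []
    for b in range(config.env_gradients):
        if b == 0:
            base = cx / width * 100.0
        elif b == 1:
            base = cy / height * 100.0
        else:
            base = 50.0 + 50.0 * np.sin(2 * np.pi * (b - 1) * cx / width)
        if config.noise_sd > 0:
            base = base + rng.normal(0.0, config.noise_sd, base.shape)
        bands.append(RasterGrid(base.astype(np.float32), tr))
        names.append(f"env_{b + 1}")
    stack = RasterStack(bands, names)

    region_ids = np.clip(np.floor(cx / B).astype(int), 0, n - 1) + 1
    region_raster = RasterGrid(region_ids.astype(np.float32), tr)
    truth = SyntheticTruth(region_raster, species_region, species_centers, region_bounds)
    return occ, tree, stack, area, truth
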