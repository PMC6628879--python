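"""Regular georeferenced grids and GeoTIFF input/output.

Rasters are modelled as north-up regular grids: an affine transform of the
restricted form ``x = x0 + col*dx``, ``y = y0 + row*dy`` with ``dx > 0`` and
``dy < 0`` (row index increases southward).  Files are read and written as
GeoTIFF using the ModelPixelScale / ModelTiepoint tags plus the GDAL nodata
convention, so outputs open in any GIS.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np
import tifffile

from ..errors import AlignmentError, RasterFormatError

DEFAULT_NODATA = -9999.0

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridTransform:
    """Affine cell→world mapping for a north-up grid.

    ``(x0, y0)`` is the outer corner of cell (row=0, col=0); cell centers sit
    half a cell inward.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self):
        if not (math.isfinite(self.dx) and math.isfinite(self.dy)):
            raise RasterFormatError("non-finite cell size")
        if self.dx <= 0 or self.dy >= 0:
            raise RasterFormatError(
                f"transform must have dx > 0 and dy < 0, got dx={self.dx}, dy={self.dy}"
            )

    def cell_center(self, row, col):
        """World coordinates of cell centers (vectorised)."""
        row = np.asarray(row)
        col = np.asarray(col)
        return self.x0 + (col + 0.5) * self.dx, self.y0 + (row + 0.5) * self.dy

    def rowcol(self, x, y):
        """Cell indices containing world points (floor convention)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.dx).astype(int)
        row = np.floor((y - self.y0) / self.dy).astype(int)
        return row, col

    def close_to(self, other: "GridTransform", rtol: float = 1e-9) -> bool:
        scale = max(abs(self.dx), abs(self.dy), 1e-30)
        return (
            abs(self.x0 - other.x0) <= rtol * max(abs(self.x0), scale)
            and abs(self.y0 - other.y0) <= rtol * max(abs(self.y0), scale)
            and abs(self.dx - other.dx) <= rtol * scale
            and abs(self.dy - other.dy) <= rtol * scale
        )


@dataclass
class RasterGrid:
    """A single-band regular grid with a nodata sentinel."""

    values: np.ndarray
    transform: GridTransform
    nodata: float = DEFAULT_NODATA
    crs: str | None = None
    name: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise RasterFormatError(f"expected 2-D values, got shape {self.values.shape}")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata, finite) cells."""
        v = self.values
        ok = np.isfinite(v)
        if self.nodata is not None:
            ok &= v != np.float32(self.nodata)
        return ok

    @property
    def cell_area(self) -> float:
        return self.transform.dx * abs(self.transform.dy)

    def cell_centers(self):
        """(xs, ys) 2-D arrays of every cell center."""
        rows, cols = np.mgrid[0 : self.nrows, 0 : self.ncols]
        return self.transform.cell_center(rows, cols)

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid].astype(float)

    def like(self, values: np.ndarray, name: str | None = None) -> "RasterGrid":
        """New grid with the same geometry and different values."""
        values = np.asarray(values, dtype=np.float32)
        if values.shape != self.values.shape:
            raise AlignmentError(
                f"shape {values.shape} does not match grid {self.values.shape}"
            )
        return RasterGrid(values, self.transform, self.nodata, self.crs, name)

    def filled(self, fill=np.nan) -> np.ndarray:
        out = self.values.astype(float)
        out[~self.valid] = fill
        return out

    def sample(self, x, y):
        """Values at world points by cell-center containment; NaN off grid."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        row, col = self.transform.rowcol(x, y)
        ok = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        out = np.full(x.shape, np.nan)
        valid = self.valid
        rr, cc = row[ok], col[ok]
        vals = self.values[rr, cc].astype(float)
        vals[~valid[rr, cc]] = np.nan
        out[ok] = vals
        return out

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and self.transform.close_to(other.transform)
        )


def grid_from_bounds(
    xmin: float,
    ymin: float,
    xmax: float,
    ymax: float,
    res: float,
    nodata: float = DEFAULT_NODATA,
    crs: str | None = None,
) -> RasterGrid:
    """Empty (all-nodata) grid covering a bounding box at cell size ``res``."""
    if res <= 0:
        raise RasterFormatError("resolution must be positive")
    if xmax <= xmin or ymax <= ymin:
        raise RasterFormatError("empty bounding box")
    ncols = max(1, int(math.ceil((xmax - xmin) / res - 1e-9)))
    nrows = max(1, int(math.ceil((ymax - ymin) / res - 1e-9)))
    tr = GridTransform(xmin, ymin + nrows * res, res, -res)
    values = np.full((nrows, ncols), nodata, dtype=np.float32)
    return RasterGrid(values, tr, nodata=nodata, crs=crs)


class RasterStack:
    """Ordered, cell-aligned bands sharing one transform/extent/crs."""

    def __init__(self, grids: list[RasterGrid], names: list[str] | None = None):
        if not grids:
            raise RasterFormatError("empty stack")
        ref = grids[0]
        for g in grids[1:]:
            if not ref.aligned_with(g):
                raise AlignmentError("stack bands are not cell-aligned")
        if names is None:
            names = [g.name or f"band_{i + 1}" for i, g in enumerate(grids)]
        if len(names) != len(grids):
            raise RasterFormatError("band count and name count differ")
        if len(set(names)) != len(names):
            raise RasterFormatError("duplicate band names")
        self.grids = list(grids)
        self.names = list(names)
        for g, n in zip(self.grids, self.names):
            g.name = n

    def __len__(self) -> int:
        return len(self.grids)

    def __getitem__(self, key) -> RasterGrid:
        if isinstance(key, str):
            return self.grids[self.names.index(key)]
        return self.grids[key]

    @property
    def transform(self) -> GridTransform:
        return self.grids[0].transform

    @property
    def crs(self):
        return self.grids[0].crs

    @property
    def shape(self):
        return self.grids[0].values.shape

    def values3d(self) -> np.ndarray:
        return np.stack([g.values for g in self.grids])

    def joint_valid(self) -> np.ndarray:
        """Cells valid in every band."""
        ok = self.grids[0].valid
        for g in self.grids[1:]:
            ok = ok & g.valid
        return ok

    def any_valid(self) -> np.ndarray:
        ok = self.grids[0].valid
        for g in self.grids[1:]:
            ok = ok | g.valid
        return ok

    def table(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_cells, n_bands) float array over ``mask`` (default joint-valid)."""
        if mask is None:
            mask = self.joint_valid()
        return np.column_stack([g.values[mask].astype(float) for g in self.grids])


def write_raster(grid: RasterGrid | RasterStack, path: str | os.PathLike) -> None:
    """Write a grid or stack as GeoTIFF (float32, georeferencing tags)."""
    if isinstance(grid, RasterStack):
        data = grid.values3d()
        meta = {"crs": grid.crs, "band_names": grid.names, "nodata": grid.grids[0].nodata}
        tr = grid.transform
        nodata = grid.grids[0].nodata
    else:
        data = grid.values
        meta = {"crs": grid.crs, "band_names": [grid.name or "band_1"], "nodata": grid.nodata}
        tr = grid.transform
        nodata = grid.nodata
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(tr.dx), float(-tr.dy), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(tr.x0), float(tr.y0), 0.0)),
        (_TAG_GDAL_NODATA, "s", None, str(nodata)),
    ]
    tifffile.imwrite(
        os.fspath(path),
        data.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
        extratags=extratags,
    )


def _read_tiff(path) -> tuple[np.ndarray, GridTransform, float, dict]:
    try:
        with tifffile.TiffFile(os.fspath(path)) as tf:
            page = tf.pages[0]
            data = tf.asarray()
            tags = page.tags
            scale = tags.valueof(_TAG_MODEL_PIXEL_SCALE)
            tie = tags.valueof(_TAG_MODEL_TIEPOINT)
            nodata_s = tags.valueof(_TAG_GDAL_NODATA)
            desc = tags.valueof("ImageDescription")
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise RasterFormatError(f"cannot read {path!r} as GeoTIFF: {exc}") from exc
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if scale is not None and tie is not None:
        tr = GridTransform(float(tie[3]), float(tie[4]), float(scale[0]), -float(scale[1]))
    else:
        tr = GridTransform(0.0, float(data.shape[-2]), 1.0, -1.0)
    nodata = DEFAULT_NODATA
    if nodata_s is not None:
        nodata = float(str(nodata_s).strip("\x00 "))
    elif "nodata" in meta and meta["nodata"] is not None:
        nodata = float(meta["nodata"])
    return np.asarray(data), tr, nodata, meta


def read_raster(path: str | os.PathLike, reference: RasterGrid | None = None) -> RasterGrid:
    """Read a single-band GeoTIFF; multi-band files yield the first band.

    When ``reference`` is given the result must align with it cell-for-cell.
    """
    data, tr, nodata, meta = _read_tiff(path)
    if data.ndim == 3:
        data = data[0]
    names = meta.get("band_names") or [None]
    grid = RasterGrid(data, tr, nodata=nodata, crs=meta.get("crs"), name=names[0])
    if reference is not None and not grid.aligned_with(reference):
        raise AlignmentError(f"{path!r} does not align with the reference grid")
    return grid


def read_stack(path: str | os.PathLike) -> RasterStack:
    """Read a multi-band GeoTIFF as a stack (single band → 1-band stack)."""
    data, tr, nodata, meta = _read_tiff(path)
    if data.ndim == 2:
        data = data[None]
    names = meta.get("band_names")
    if not names or len(names) != data.shape[0]:
        names = [f"band_{i + 1}" for i in range(data.shape[0])]
    grids = [
        RasterGrid(data[i], tr, nodata=nodata, crs=meta.get("crs"), name=names[i])
        for i in range(data.shape[0])
    ]
    return RasterStack(grids, names)


def read_stack_dir(path: str | os.PathLike) -> RasterStack:
    """Read every ``*.tif``/``*.tiff`` in a directory as one aligned stack.

    Band name = file stem; files sorted by name for reproducibility.
    """
    files = sorted(
        f for f in os.listdir(path) if f.lower().endswith((".tif", ".tiff"))
    )
    if not files:
        raise RasterFormatError(f"no GeoTIFF files in {path!r}")
    grids, names = [], []
    for f in files:
        g = read_raster(os.path.join(path, f))
        g.name = os.path.splitext(f)[0]
        grids.append(g)
        names.append(g.name)
    return RasterStack(grids, names)


def stack_from_array(
    arr: np.ndarray,
    transform: GridTransform,
    names: list[str] | None = None,
    nodata: float = DEFAULT_NODATA,
    crs: str | None = None,
) -> RasterStack:
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    grids = [RasterGrid(arr[i], transform, nodata=nodata, crs=crs) for i in range(arr.shape[0])]
    return RasterStack(grids, names)
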