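"""Study-area masks: GeoJSON (full support) and a minimal ESRI shapefile reader.

Only polygon geometry is accepted.  Invalid rings are repaired with a
zero-width buffer and a warning; unrepairable geometry raises.
"""

from __future__ import annotations

import json
import os
import struct
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
import shapely.geometry as sgeom
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from ..errors import DroppedDataWarning, GeometryError


@dataclass
class StudyArea:
    """One or more simple polygons (holes allowed) with a CRS tag."""

    geometry: BaseGeometry
    crs: str | None = None

    def __post_init__(self):
        geom = self.geometry
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise GeometryError(f"study area must be polygonal, got {geom.geom_type}")
        if not geom.is_valid:
            repaired = geom.buffer(0)
            if repaired.is_valid and repaired.geom_type in ("Polygon", "MultiPolygon"):
                warnings.warn("repaired invalid study-area rings", DroppedDataWarning, stacklevel=2)
                self.geometry = repaired
            else:
                raise GeometryError("study-area polygon is invalid and could not be repaired")
        if self.geometry.area <= 0:
            raise GeometryError("study area has zero area")

    @property
    def area(self) -> float:
        return self.geometry.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.geometry.bounds

    def contains_xy(self, x, y) -> np.ndarray:
        """Vectorised boundary-inclusive point-in-area test."""
        return shapely.intersects_xy(self.geometry, np.asarray(x, float), np.asarray(y, float))

    def to_geojson(self, path: str | os.PathLike) -> None:
        feature = {
            "type": "Feature",
            "properties": {"crs": self.crs},
            "geometry": sgeom.mapping(self.geometry),
        }
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": [feature]}, fh)


def _polygons_from_geojson(obj) -> list[BaseGeometry]:
    t = obj.get("type")
    if t == "FeatureCollection":
        out = []
        for feat in obj.get("features", []):
            out.extend(_polygons_from_geojson(feat))
        return out
    if t == "Feature":
        return _polygons_from_geojson(obj["geometry"])
    if t == "GeometryCollection":
        out = []
        for g in obj.get("geometries", []):
            out.extend(_polygons_from_geojson(g))
        return out
    geom = sgeom.shape(obj)
    if geom.geom_type == "Polygon":
        return [geom]
    if geom.geom_type == "MultiPolygon":
        return list(geom.geoms)
    raise GeometryError(f"expected polygon geometry, got {geom.geom_type}")


def _ring_signed_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _read_shapefile_polygons(path) -> list[BaseGeometry]:
    # .shp binary layout: 100-byte header, then (rec header BE, content LE).
    # Shape type 5/15/25 = Polygon; rings CW = shell, CCW = hole.
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 100:
        raise GeometryError(f"{path!r} is not a shapefile")
    (magic,) = struct.unpack(">i", data[:4])
    if magic != 9994:
        raise GeometryError(f"{path!r} is not a shapefile (bad magic)")
    (shp_type,) = struct.unpack("<i", data[32:36])
    if shp_type not in (5, 15, 25):
        raise GeometryError(f"shapefile geometry type {shp_type} is not polygon")
    shells: list[tuple[np.ndarray, list]] = []
    holes: list[np.ndarray] = []
    pos = 100
    while pos + 8 <= len(data):
        (_, length) = struct.unpack(">ii", data[pos : pos + 8])
        content = data[pos + 8 : pos + 8 + 2 * length]
        pos += 8 + 2 * length
        (rec_type,) = struct.unpack("<i", content[:4])
        if rec_type == 0:  # null shape
            continue
        n_parts, n_points = struct.unpack("<ii", content[36:44])
        parts = struct.unpack(f"<{n_parts}i", content[44 : 44 + 4 * n_parts])
        pts_off = 44 + 4 * n_parts
        pts = np.frombuffer(
            content[pts_off : pts_off + 16 * n_points], dtype="<f8"
        ).reshape(n_points, 2)
        bounds = list(parts) + [n_points]
        for i in range(n_parts):
            ring = pts[bounds[i] : bounds[i + 1]]
            if len(ring) < 4:
                continue
            if _ring_signed_area(ring) < 0:  # CW in shapefile = shell
                shells.append((ring, []))
            else:
                holes.append(ring)
    if not shells:
        raise GeometryError(f"no polygon rings in {path!r}")
    shell_polys = [sgeom.Polygon(s) for s, _ in shells]
    for hole in holes:
        pt = sgeom.Point(hole[0])
        for i, sp in enumerate(shell_polys):
            if sp.contains(pt) or sp.exterior.distance(pt) == 0:
                shells[i][1].append(hole)
                break
    return [sgeom.Polygon(s, h) for (s, h) in shells]


def read_mask(path: str | os.PathLike, crs: str | None = None) -> StudyArea:
    """Read a polygon mask from GeoJSON (``.json``/``.geojson``) or ``.shp``."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".shp":
        polys = _read_shapefile_polygons(path)
    else:
        with open(path) as fh:
            try:
                obj = json.load(fh)
            except json.JSONDecodeError as exc:
                raise GeometryError(f"{path!r} is not valid GeoJSON: {exc}") from exc
        polys = _polygons_from_geojson(obj)
    merged = unary_union(polys)
    return StudyArea(merged, crs=crs)


def write_polygons_geojson(
    path: str | os.PathLike, geometries: list[BaseGeometry], properties: list[dict] | None = None
) -> None:
    """Write polygons (one feature each) to a GeoJSON FeatureCollection."""
    if properties is None:
        properties = [{} for _ in geometries]
    feats = [
        {"type": "Feature", "properties": p, "geometry": sgeom.mapping(g)}
        for g, p in zip(geometries, properties)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
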