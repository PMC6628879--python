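"""Species occurrence tables: delimited text with columns sp, x, y."""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import DroppedDataWarning, EmptyInputError, SchemaError

_GEOGRAPHIC_TAGS = {"epsg:4326", "wgs84", "degrees", "geographic"}


@dataclass
class OccurrenceTable:
    """Point records of species in planar (or degree) coordinates.

    ``species``, ``x``, ``y`` are parallel arrays; coordinates are treated as
    planar for all distance computation.  Duplicate (species, x, y) rows are
    permitted but counted in :attr:`n_duplicates`.
    """

    species: np.ndarray
    x: np.ndarray
    y: np.ndarray
    crs: str | None = None
    n_dropped: int = 0
    n_duplicates: int = field(init=False, default=0)

    def __post_init__(self):
        self.species = np.asarray(self.species, dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.species) == len(self.x) == len(self.y)):
            raise SchemaError("species, x, y must have equal length")
        if len(self.species) == 0:
            raise EmptyInputError("occurrence table has no records")
        if any(s is None or (isinstance(s, str) and not s.strip()) for s in self.species):
            raise SchemaError("missing species labels")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise SchemaError("non-finite coordinates")
        df = pd.DataFrame({"sp": self.species, "x": self.x, "y": self.y})
        self.n_duplicates = int(df.duplicated().sum())
        if self.n_duplicates:
            warnings.warn(
                f"{self.n_duplicates} duplicate (species,x,y) records",
                DroppedDataWarning,
                stacklevel=2,
            )
        if self.crs and self.crs.lower() in _GEOGRAPHIC_TAGS:
            warnings.warn(
                "coordinates are geographic degrees; distances will be computed "
                "in degree space — supply an equal-area CRS if that is not intended",
                DroppedDataWarning,
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.species)

    @property
    def species_names(self) -> list[str]:
        """Unique species labels in first-appearance order."""
        return list(pd.unique(self.species))

    def subset(self, species: str) -> "OccurrenceTable":
        m = self.species == species
        if not m.any():
            raise EmptyInputError(f"no records for species {species!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DroppedDataWarning)
            return OccurrenceTable(self.species[m], self.x[m], self.y[m], crs=self.crs)

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sp": self.species, "x": self.x, "y": self.y})

    def to_csv(self, path: str | os.PathLike, delimiter: str = ",") -> None:
        self.to_frame().to_csv(path, index=False, sep=delimiter)


def read_occurrences(
    path: str | os.PathLike, delimiter: str = ",", crs: str | None = None
) -> OccurrenceTable:
    """Read a sp/x/y delimited file into an :class:`OccurrenceTable`.

    Column matching is case-insensitive and order-free; extra columns are
    ignored.  Rows with unparseable coordinates or empty species labels are
    dropped with a warning that reports the count.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path!r} is empty") from None
    cols = {c.strip().lower(): c for c in df.columns}
    for required in ("sp", "x", "y"):
        if required not in cols:
            raise SchemaError(f"missing required column {required!r} in {path!r}")
    sp = df[cols["sp"]].astype(object)
    x = pd.to_numeric(df[cols["x"]], errors="coerce")
    y = pd.to_numeric(df[cols["y"]], errors="coerce")
    ok = x.notna() & y.notna() & np.isfinite(x.fillna(np.nan)) & np.isfinite(y.fillna(np.nan))
    ok &= sp.notna() & (sp.astype(str).str.strip() != "")
    n_dropped = int((~ok).sum())
    if ok.sum() == 0:
        raise EmptyInputError(f"no valid occurrence rows in {path!r}")
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} malformed occurrence rows", DroppedDataWarning, stacklevel=2
        )
    table = OccurrenceTable(
        sp[ok].to_numpy(), x[ok].to_numpy(float), y[ok].to_numpy(float), crs=crs
    )
    table.n_dropped = n_dropped
    return table
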