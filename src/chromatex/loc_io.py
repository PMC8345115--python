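"""Read/write single-molecule localisation tables and nuclear ROI polygons.

Localisation tables are the point lists produced by SMLM fitting software
(one row per detected blinking event, coordinates in nanometres).  The
default CSV dialect matches ThunderSTORM export headers
(``frame``, ``x [nm]``, ``y [nm]``, ``intensity [photon]``).

Coordinates are continuous nm with the origin at the image top-left,
x rightward and y downward.  Points exactly on an ROI edge or vertex count
as inside the ROI: localisations are never silently dropped at a boundary.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import IO, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .exceptions import FormatError, GeometryError, ParseError

#: maps internal field names to ThunderSTORM CSV column headers
DEFAULT_DIALECT: dict[str, str] = {
    "frame": "frame",
    "x_nm": "x [nm]",
    "y_nm": "y [nm]",
    "intensity": "intensity [photon]",
    "uncertainty_nm": "uncertainty [nm]",
}

_MANDATORY = ("frame", "x_nm", "y_nm")


@dataclass(frozen=True)
class LocalisationTable:
    """Point list of blinking events; the substrate of all SMLM analyses.

    Parameters
    ----------
    frame : array of int
        Acquisition frame of each event (1-based).
    x_nm, y_nm : array of float
        Event coordinates in nanometres (finite, non-negative).
    intensity : array of float, optional
        Photon-count estimate per event (arbitrary units).
    uncertainty_nm : array of float, optional
        Lateral localisation precision per event.
    """

    frame: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    intensity: np.ndarray | None = None
    uncertainty_nm: np.ndarray | None = None

    def __post_init__(self):
        frame = np.asarray(self.frame, dtype=np.int64)
        x = np.asarray(self.x_nm, dtype=float)
        y = np.asarray(self.y_nm, dtype=float)
        if not (frame.shape == x.shape == y.shape) or frame.ndim != 1:
            raise FormatError("frame, x_nm and y_nm must be 1-D arrays of equal length")
        if x.size and (not np.isfinite(x).all() or not np.isfinite(y).all()):
            raise FormatError("coordinates must be finite")
        if x.size and (x.min() < 0 or y.min() < 0):
            raise FormatError("coordinates must be non-negative")
        if frame.size and frame.min() < 1:
            raise FormatError("frame numbers must be >= 1")
        object.__setattr__(self, "frame", frame)
        object.__setattr__(self, "x_nm", x)
        object.__setattr__(self, "y_nm", y)
        for name in ("intensity", "uncertainty_nm"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape != x.shape:
                    raise FormatError(f"{name} length does not match coordinates")
                object.__setattr__(self, name, val)

    def __len__(self) -> int:
        return self.x_nm.size

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array in nm."""
        return np.column_stack([self.x_nm, self.y_nm])

    def select(self, mask: np.ndarray) -> "LocalisationTable":
        """Row subset preserving input order."""
        return LocalisationTable(
            self.frame[mask],
            self.x_nm[mask],
            self.y_nm[mask],
            None if self.intensity is None else self.intensity[mask],
            None if self.uncertainty_nm is None else self.uncertainty_nm[mask],
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {"frame": self.frame, "x_nm": self.x_nm, "y_nm": self.y_nm}
        if self.intensity is not None:
            data["intensity"] = self.intensity
        if self.uncertainty_nm is not None:
            data["uncertainty_nm"] = self.uncertainty_nm
        return pd.DataFrame(data)


@dataclass(frozen=True)
class RoiPolygon:
    """Simple polygon in nm delimiting one nucleus (implicitly closed)."""

    vertices: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise GeometryError("vertices must be an (n, 2) array")
        if v.shape[0] < 3:
            raise GeometryError("a polygon needs at least 3 vertices")
        if not np.isfinite(v).all():
            raise GeometryError("polygon vertices must be finite")
        object.__setattr__(self, "vertices", v)
        poly = Polygon(v)
        if not poly.is_valid or not poly.is_simple:
            raise GeometryError("polygon must be simple (no self-intersection)")
        if poly.area <= 0:
            raise GeometryError("polygon must enclose a positive area")

    @cached_property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])

    def contains(self, x_nm, y_nm) -> np.ndarray:
        """Vectorised boundary-inclusive point-in-polygon test."""
        pts = shapely.points(np.column_stack(
            [np.atleast_1d(np.asarray(x_nm, dtype=float)),
             np.atleast_1d(np.asarray(y_nm, dtype=float))]))
        return shapely.covers(self.polygon, pts)


def read_localisations(
    source: str | Path | IO[str],
    dialect: Mapping[str, str] | None = None,
) -> LocalisationTable:
    """Parse a localisation CSV (header row, comma-separated).

    ``dialect`` maps internal field names (``frame``, ``x_nm``, ``y_nm``,
    ``intensity``, ``uncertainty_nm``) to the file's column headers; defaults
    to the ThunderSTORM export convention.  Header strings are matched
    exactly after whitespace trimming; unknown columns are ignored.
    """
    names = dict(DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    df.columns = [str(c).strip().strip('"') for c in df.columns]
    for fld in _MANDATORY:
        if names[fld] not in df.columns:
            raise FormatError(f"missing mandatory column {names[fld]!r}")

    def _numeric(col: str, fld: str) -> np.ndarray:
        raw = df[col]
        out = pd.to_numeric(raw, errors="coerce")
        bad = out.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1  # 1-based data row
            raise ParseError(
                f"non-numeric value {raw.iloc[row - 1]!r} in column {col!r} "
                f"(data row {row})", row=row)
        if out.isna().any():
            row = int(np.flatnonzero(out.isna().to_numpy())[0]) + 1
            raise ParseError(f"empty value in column {col!r} (data row {row})", row=row)
        return out.to_numpy(dtype=float)

    kwargs = {}
    for fld in ("intensity", "uncertainty_nm"):
        if names[fld] in df.columns:
            kwargs[fld] = _numeric(names[fld], fld)
    return LocalisationTable(
        frame=_numeric(names["frame"], "frame").astype(np.int64),
        x_nm=_numeric(names["x_nm"], "x_nm"),
        y_nm=_numeric(names["y_nm"], "y_nm"),
        **kwargs,
    )


def write_localisations(
    table: LocalisationTable,
    dest: str | Path | IO[str],
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write a localisation table as CSV in the given dialect (default ThunderSTORM)."""
    names = dict(DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    df = table.to_dataframe()
    df.columns = [names.get(c, c) for c in df.columns]
    df.to_csv(dest, index=False)


def filter_by_roi(table: LocalisationTable, roi: RoiPolygon) -> LocalisationTable:
    """Restrict a table to events inside the ROI (boundary-inclusive, order kept)."""
    if len(table) == 0:
        return table
    return table.select(roi.contains(table.x_nm, table.y_nm))


def roi_area(roi: RoiPolygon) -> float:
    """Shoelace area of the polygon in square micrometres (orientation-free)."""
    v = roi.vertices
    x, y = v[:, 0], v[:, 1]
    area_nm2 = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area_nm2 / 1e6)


def read_roi(source: str | Path | IO[str]) -> RoiPolygon:
    """Load an ROI polygon from JSON ``{"vertices": [[x, y], ...], "units": "nm"}``."""
    if hasattr(source, "read"):
        data = json.load(source)
    else:
        with open(source) as fh:
            data = json.load(fh)
    if "vertices" not in data:
        raise FormatError("ROI JSON must contain a 'vertices' key")
    units = data.get("units", "nm")
    if units != "nm":
        raise FormatError(f"unsupported ROI units {units!r} (expected 'nm')")
    return RoiPolygon(np.asarray(data["vertices"], dtype=float))


def write_roi(roi: RoiPolygon, dest: str | Path | IO[str]) -> None:
    payload = {"vertices": roi.vertices.tolist(), "units": "nm"}
    if hasattr(dest, "write"):
        json.dump(payload, dest)
    else:
        with open(dest, "w") as fh:
            json.dump(payload, fh)
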