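"""Localization tables and the core 3D point-cloud container.

Single-molecule localisation microscopy (SMLM) software emits one row per
fitted emitter position.  This module defines :class:`LocalizationCloud`,
the universal input of the package, and readers/writers for the de-facto
delimited-text "localization table" format (rapidSTORM / ThunderSTORM
style: a header line followed by numeric columns, at least x, y and in 3D
mode z, in nanometres after scaling).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LocalizationCloud",
    "read_localizations",
    "write_localizations",
    "sample_global_density",
    "FormatError",
    "EmptyInputError",
    "DegenerateGeometryError",
]


class FormatError(ValueError):
    """A required column is missing or the table cannot be parsed."""


class EmptyInputError(ValueError):
    """No valid localization rows were found."""


class DegenerateGeometryError(ValueError):
    """The cloud's bounding box has zero extent along a required axis."""


class LocalizationCloud:
    """A cloud of localisation events in nanometres.

    Parameters
    ----------
    points
        ``(n, 3)`` float array of coordinates in nm.  In 2D mode the z
        column is exactly zero.
    meta
        Optional per-point metadata columns (frame, intensity,
        uncertainty, ...), each of length ``n``.
    dim_mode
        ``"3D"`` (default) or ``"2D"``.
    """

    def __init__(self, points, meta: pd.DataFrame | None = None, dim_mode: str = "3D"):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if pts.shape[0] < 1:
            raise EmptyInputError("a LocalizationCloud needs at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("coordinates must be finite")
        if dim_mode not in ("2D", "3D"):
            raise ValueError("dim_mode must be '2D' or '3D'")
        if dim_mode == "2D" and np.any(pts[:, 2] != 0.0):
            raise ValueError("2D mode requires all z coordinates to be 0")
        if meta is not None and len(meta) != len(pts):
            raise ValueError("meta must have one row per point")
        self.points = pts
        self.meta = meta
        self.dim_mode = dim_mode

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def __len__(self) -> int:
        return self.n

    @property
    def bounding_box(self) -> np.ndarray:
        """Axis-aligned extents (max - min) along x, y, z in nm."""
        return self.points.max(axis=0) - self.points.min(axis=0)

    @property
    def volume(self) -> float:
        """Volume of the axis-aligned bounding box (nm^3)."""
        ext = self.bounding_box
        if self.dim_mode == "2D":
            ext = ext[:2]
        return float(np.prod(ext))

    def subset(self, index: np.ndarray) -> "LocalizationCloud":
        """Return the cloud restricted to the given integer/boolean index."""
        meta = self.meta.iloc[np.asarray(index)].reset_index(drop=True) if self.meta is not None else None
        return LocalizationCloud(self.points[index], meta=meta, dim_mode=self.dim_mode)


_KNOWN_META = ("frame", "intensity", "uncertainty_xy", "uncertainty_z")


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    for delim in (",", "\t", ";"):
        if delim in header:
            return delim
    return ","


def read_localizations(
    path,
    column_map: Mapping[str, str] | None = None,
    units_scale: float = 1.0,
    dim_mode: str = "3D",
) -> LocalizationCloud:
    """Read a delimited localization table into a :class:`LocalizationCloud`.

    Parameters
    ----------
    path
        CSV/TSV/semicolon-delimited file with a header line.
    column_map
        Maps canonical names (``x``, ``y``, ``z``, ``frame``, ...) to the
        file's column names.  Identity by default.
    units_scale
        Multiplicative factor applied to coordinates to bring them to nm
        (e.g. 1000 for a table in micrometres).  Never inferred.
    dim_mode
        In ``"2D"`` mode a missing z column is padded with zeros.

    Raises
    ------
    FormatError
        If a mapped coordinate column is absent, or more than half of the
        rows have non-numeric coordinates.
    EmptyInputError
        If no valid rows remain.
    """
    path = Path(path)
    if units_scale <= 0:
        raise ValueError("units_scale must be positive")
    column_map = dict(column_map or {})
    delim = _sniff_delimiter(path)
    table = pd.read_csv(path, sep=delim)
    table.columns = [str(c).strip() for c in table.columns]

    def col(name: str) -> str:
        return column_map.get(name, name)

    coord_cols = ["x", "y"] + (["z"] if dim_mode == "3D" else [])
    for c in coord_cols:
        if col(c) not in table.columns:
            raise FormatError(f"required column {col(c)!r} not found in {path.name}")
    use_z = dim_mode == "3D" or col("z") in table.columns

    n_raw = len(table)
    coords = pd.DataFrame(
        {c: pd.to_numeric(table[col(c)], errors="coerce") for c in (["x", "y", "z"] if use_z else ["x", "y"])}
    )
    valid = np.isfinite(coords.to_numpy(dtype=float)).all(axis=1)
    n_bad = int(n_raw - valid.sum())
    if valid.sum() == 0:
        raise EmptyInputError(f"no valid localization rows in {path.name}")
    if n_bad > 0.5 * n_raw:
        raise FormatError(f"{n_bad}/{n_raw} rows rejected (non-numeric coordinates)")
    if n_bad:
        warnings.warn(f"{n_bad} malformed row(s) rejected while reading {path.name}")

    pts = np.zeros((int(valid.sum()), 3))
    pts[:, 0] = coords.loc[valid, "x"].to_numpy()
    pts[:, 1] = coords.loc[valid, "y"].to_numpy()
    if use_z:
        pts[:, 2] = coords.loc[valid, "z"].to_numpy()
    pts *= units_scale
    if dim_mode == "2D":
        pts[:, 2] = 0.0

    used = {col(c) for c in (["x", "y", "z"] if use_z else ["x", "y"])}
    meta_cols = [c for c in table.columns if c not in used]
    meta = table.loc[valid, meta_cols].reset_index(drop=True) if meta_cols else None
    return LocalizationCloud(pts, meta=meta, dim_mode=dim_mode)


def write_localizations(cloud: LocalizationCloud, path) -> int:
    """Write the cloud as a CSV localization table; returns rows written.

    Round-tripping through :func:`read_localizations` reproduces the
    coordinates to better than 1e-6 nm (full double precision is written).
    """
    path = Path(path)
    out = pd.DataFrame(cloud.points, columns=["x", "y", "z"])
    if cloud.meta is not None:
        for c in cloud.meta.columns:
            out[c] = cloud.meta[c].to_numpy()
    out.to_csv(path, index=False, float_format="%.9g")
    return len(out)


def sample_global_density(cloud: LocalizationCloud) -> float:
    """Whole-sample density N/V in points per nm^3 (per nm^2 in 2D mode).

    V is the volume of the axis-aligned bounding box of the analysed
    cloud; a zero-extent box raises :class:`DegenerateGeometryError`.
    """
    V = cloud.volume
    if V <= 0:
        raise DegenerateGeometryError("bounding box has zero extent; density undefined")
    return cloud.n / V
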