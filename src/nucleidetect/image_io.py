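"""Volumetric image and centroid-table I/O.

This module owns the coordinate conventions used throughout the package:

* volumes are stored as 3D arrays indexed ``data[x, y, z]``, with ``z`` the
  optical slicing axis (the page axis of a multi-page TIFF);
* coordinates are 0-based and voxel-centered;
* voxel sizes are ``(dx, dy, dz)`` in micrometres.

Centroid tables are plain CSV/TSV text with columns ``x, y, z, t`` and an
optional ``id`` column; they are carried in memory as pandas DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

CENTROID_COLUMNS = ("x", "y", "z", "t")


@dataclass
class Volume:
    """One 3D grayscale frame of a time series.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities, arbitrary units, non-negative and finite.
    voxel_size : tuple of float
        Physical voxel extents ``(dx, dy, dz)`` in µm.
    t : int
        0-based time index of the frame within its sequence.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    t: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size components must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def astype_float(self) -> "Volume":
        """Return a copy with float64 data (internal math is floating point)."""
        return Volume(self.data.astype(np.float64, copy=True), self.voxel_size, self.t)


def read_stack(path: str | Path, voxel_size=(1.0, 1.0, 1.0), t: int = 0) -> Volume:
    """Read a multi-page TIFF into a :class:`Volume`.

    The TIFF page axis becomes the z axis; page rows/columns map to y/x so
    that the in-memory array is indexed ``data[x, y, z]``.  Integer inputs
    are preserved bit-exact.
    """
    try:
        arr = tifffile.imread(str(path))
    except (OSError, ValueError) as exc:  # unreadable / malformed container
        raise IOError(f"cannot read TIFF stack {path!r}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"{path!r}: expected a 3D stack, got shape {arr.shape}")
    # (z, y, x) -> (x, y, z)
    return Volume(np.ascontiguousarray(arr.T), voxel_size=voxel_size, t=t)


def write_stack(path: str | Path, v: Volume) -> None:
    """Write a :class:`Volume` as a multi-page TIFF (pages along z)."""
    tifffile.imwrite(str(path), np.ascontiguousarray(v.data.T))


def read_centroids(path: str | Path, origin: int = 0) -> pd.DataFrame:
    """Read a centroid table (whitespace- or comma-delimited text).

    Columns ``x, y, z, t`` are required (header optional; column order is
    assumed when absent), ``id`` and extra columns are kept when present.
    ``origin=1`` shifts 1-based coordinates produced by other software to
    this package's 0-based convention.
    """
    path = Path(path)
    text = path.read_text()
    rows: list[list[str]] = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        rows.append([f for f in ln.replace(",", " ").split() if f])
    if not rows:
        return pd.DataFrame(columns=list(CENTROID_COLUMNS))

    header: list[str] | None = None
    first = rows[0]
    if any(not _is_number(f) for f in first):
        header = [f.lower() for f in first]
        rows = rows[1:]
    if header is None:
        ncol = len(first)
        header = list(CENTROID_COLUMNS) + (["id"] if ncol >= 5 else [])
        header += [f"extra{i}" for i in range(len(header), ncol)]

    data: list[list[float]] = []
    for i, row in enumerate(rows):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: line {i + 2 if first is not row else i + 1}: "
                f"expected {len(header)} fields, got {len(row)}"
            )
        try:
            data.append([float(f) for f in row])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed row {row!r}: {exc}") from exc
    df = pd.DataFrame(data, columns=header)
    missing = [c for c in CENTROID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if origin:
        df[["x", "y", "z"]] -= origin
    df["t"] = df["t"].astype(int)
    if "id" in df.columns:
        df["id"] = df["id"].astype(int)
    return df


def write_centroids(path: str | Path, table: pd.DataFrame) -> None:
    """Write a centroid table as CSV with header."""
    table.to_csv(path, index=False)


def check_in_bounds(table: pd.DataFrame, v: Volume) -> None:
    """Raise if any centroid of frame ``v.t`` lies outside ``v``'s grid."""
    sub = table[table["t"] == v.t]
    nx, ny, nz = v.shape
    ok = (
        (sub["x"] >= 0) & (sub["x"] <= nx - 1)
        & (sub["y"] >= 0) & (sub["y"] <= ny - 1)
        & (sub["z"] >= 0) & (sub["z"] <= nz - 1)
    )
    if not bool(ok.all()):
        bad = sub[~ok]
        raise ValueError(f"{len(bad)} centroid(s) outside frame bounds {v.shape}: \n{bad}")


def to_isotropic(table: pd.DataFrame, voxel_size) -> pd.DataFrame:
    """Map native-grid z coordinates into the isotropic grid (dz' = dx).

    After cubic z-resampling the frame grid has voxel spacing ``dx`` along
    every axis; a native z index maps to ``z * dz / dx``.
    """
    dx, _dy, dz = voxel_size
    out = table.copy()
    out["z"] = out["z"] * (dz / dx)
    return out


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
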