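"""Lightweight lat/lon raster containers and plain-text grid I/O.

Rasters are regular lat/lon grids in WGS 84. Values are stored as
``(n_lat, n_lon)`` arrays (or ``(n_months, n_lat, n_lon)`` stacks) with
latitudes ascending. Cell *centers* carry the coordinates; societies are
snapped to the containing cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_grid", "write_grid"]


@dataclass
class Raster:
    """A regular lat/lon grid.

    Parameters
    ----------
    values : ndarray
        ``(n_lat, n_lon)`` grid or ``(n_months, n_lat, n_lon)`` monthly stack.
    lats, lons : ndarray
        Cell-center coordinates in decimal degrees, ascending.
    land_mask : ndarray of bool, optional
        ``(n_lat, n_lon)``; defaults to all-land (the analysis is restricted
        to continental societies, so islands/ocean are out of scope by
        default; the hook remains for masked worlds).
    """

    values: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    land_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        if self.values.shape[-2:] != (self.lats.size, self.lons.size):
            raise ValueError(
                f"grid shape {self.values.shape[-2:]} does not match "
                f"({self.lats.size}, {self.lons.size}) coordinates"
            )
        if self.land_mask is None:
            self.land_mask = np.ones((self.lats.size, self.lons.size), dtype=bool)
        else:
            self.land_mask = np.asarray(self.land_mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def n_lat(self) -> int:
        return self.lats.size

    @property
    def n_lon(self) -> int:
        return self.lons.size

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        """Index of the grid cell whose center is nearest to (lat, lon)."""
        i = int(np.argmin(np.abs(self.lats - lat)))
        j = int(np.argmin(np.abs(self.lons - lon)))
        return i, j

    def with_values(self, values: np.ndarray) -> "Raster":
        return Raster(values, self.lats, self.lons, self.land_mask)


def write_grid(path: str | Path, raster: Raster) -> None:
    """Write a raster as a whitespace text matrix plus a JSON sidecar header.

    Stacks are written with one flattened ``(n_lat * n_lon)`` row per month.
    """
    path = Path(path)
    vals = raster.values
    flat = vals.reshape(-1, raster.n_lat * raster.n_lon) if vals.ndim == 3 else vals
    np.savetxt(path, flat)
    header = {
        "lats": raster.lats.tolist(),
        "lons": raster.lons.tolist(),
        "shape": list(vals.shape),
        "land_mask": raster.land_mask.astype(int).tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header))


def read_grid(path: str | Path) -> Raster:
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    vals = np.loadtxt(path).reshape(header["shape"])
    return Raster(
        vals,
        np.asarray(header["lats"]),
        np.asarray(header["lons"]),
        np.asarray(header["land_mask"], dtype=bool),
    )
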