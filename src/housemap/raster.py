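"""Planar raster stacks for covariates, population, urban mask and country ids.

Grids live on the unit square (abstract planar coordinates, cell-registered,
north-up).  A :class:`RasterStack` is a thin wrapper around an
:class:`xarray.Dataset` whose data variables share ``(y, x)`` dimensions;
persistence uses the ESRI ASCII grid text format, one file per layer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import xarray as xr

__all__ = ["RasterStack", "read_ascii_grid", "write_ascii_grid"]

#: layer names reserved for the auxiliary (non-covariate) grids
AUX_LAYERS = ("population", "urban", "country")


@dataclass
class RasterStack:
    """Co-registered raster layers on a regular planar grid.

    Parameters
    ----------
    data : xarray.Dataset
        Data variables are the layers; coordinates ``x`` and ``y`` hold
        cell-centre positions.  Covariate layers are every variable not in
        :data:`AUX_LAYERS`.
    """

    data: xr.Dataset

    @classmethod
    def from_arrays(
        cls,
        layers: Mapping[str, np.ndarray],
        x: np.ndarray,
        y: np.ndarray,
    ) -> "RasterStack":
        ny, nx = len(y), len(x)
        for name, arr in layers.items():
            if arr.shape != (ny, nx):
                raise ValueError(
                    f"layer {name!r} has shape {arr.shape}, expected {(ny, nx)}"
                )
        ds = xr.Dataset(
            {name: (("y", "x"), np.asarray(arr)) for name, arr in layers.items()},
            coords={"x": np.asarray(x, dtype=float), "y": np.asarray(y, dtype=float)},
        )
        return cls(ds)

    # -- layer access -----------------------------------------------------
    @property
    def covariate_names(self) -> list[str]:
        return [v for v in self.data.data_vars if v not in AUX_LAYERS]

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.data.y), len(self.data.x)

    def layer(self, name: str) -> np.ndarray:
        return np.asarray(self.data[name].values)

    def covariate_matrix(self) -> np.ndarray:
        """Stack covariate layers into an ``(n_cells, n_cov)`` matrix (C order)."""
        return np.column_stack(
            [self.layer(n).ravel() for n in self.covariate_names]
        )

    def cell_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened cell-centre x and y for every cell, matching ravel order."""
        xx, yy = np.meshgrid(self.data.x.values, self.data.y.values)
        return xx.ravel(), yy.ravel()

    def same_grid(self, other: "RasterStack") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.data.x.values, other.data.x.values)
            and np.allclose(self.data.y.values, other.data.y.values)
        )

    # -- persistence ------------------------------------------------------
    def to_directory(self, path: str) -> None:
        """Write every layer as ``<path>/<layer>.asc`` (ESRI ASCII grid)."""
        os.makedirs(path, exist_ok=True)
        dx = float(self.data.x.values[1] - self.data.x.values[0]) if len(self.data.x) > 1 else 1.0
        dy = float(self.data.y.values[1] - self.data.y.values[0]) if len(self.data.y) > 1 else 1.0
        x0 = float(self.data.x.values[0]) - dx / 2
        y0 = float(self.data.y.values[0]) - dy / 2
        for name in self.data.data_vars:
            write_ascii_grid(
                os.path.join(path, f"{name}.asc"),
                self.layer(name),
                xllcorner=x0,
                yllcorner=y0,
                cellsize=(dx, dy),
            )

    @classmethod
    def from_directory(cls, path: str, names: Iterable[str] | None = None) -> "RasterStack":
        if names is None:
            names = sorted(
                f[:-4] for f in os.listdir(path) if f.endswith(".asc")
            )
        layers = {}
        header = None
        for name in names:
            arr, hdr = read_ascii_grid(os.path.join(path, f"{name}.asc"))
            if header is None:
                header = hdr
            elif arr.shape != next(iter(layers.values())).shape:
                raise ValueError(f"layer {name!r} is not co-registered")
            layers[name] = arr
        assert header is not None
        ny, nx = next(iter(layers.values())).shape
        dx = header.get("dx", header.get("cellsize", 1.0))
        dy = header.get("dy", header.get("cellsize", 1.0))
        x = header["xllcorner"] + dx * (np.arange(nx) + 0.5)
        y = header["yllcorner"] + dy * (np.arange(ny) + 0.5)
        return cls.from_arrays(layers, x=x, y=y)


def write_ascii_grid(
    path: str,
    arr: np.ndarray,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    cellsize: float | tuple[float, float] = 1.0,
    nodata: float = -9999.0,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid (row 0 = northernmost row).

    ``cellsize`` may be a (dx, dy) pair; rectangular cells use the DX/DY
    header variant.
    """
    arr = np.asarray(arr, dtype=float)
    out = np.where(np.isnan(arr), nodata, arr)
    ny, nx = arr.shape
    if isinstance(cellsize, tuple):
        dx, dy = cellsize
        cell_hdr = (f"cellsize {dx!r}\n" if dx == dy
                    else f"dx {dx!r}\ndy {dy!r}\n")
    else:
        cell_hdr = f"cellsize {cellsize!r}\n"
    with open(path, "w") as fh:
        fh.write(
            f"ncols {nx}\nnrows {ny}\nxllcorner {xllcorner!r}\n"
            f"yllcorner {yllcorner!r}\n{cell_hdr}"
            f"NODATA_value {nodata!r}\n"
        )
        # ASCII grids store the top (max-y) row first; our y axis ascends.
        np.savetxt(fh, out[::-1], fmt="%.10g")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def read_ascii_grid(path: str) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array with y ascending, header dict)."""
    header: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                key = parts[0].lower()
                header[key] = (int(parts[1]) if key in ("ncols", "nrows")
                               else float(parts[1]))
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh)
    body = np.atleast_2d(body)[::-1]
    nodata = header.get("nodata_value", -9999.0)
    body = np.where(body == nodata, np.nan, body)
    return body, header
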