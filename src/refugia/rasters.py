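"""Gridded data containers: fine climate rasters and the coarse occupancy grid.

Rasters are rectangular arrays of cell-center values, row-major from the
north-west corner (row 0 is the northernmost row).  No-data cells are NaN
in memory and the ``nodata`` sentinel on disk.  I/O uses the ESRI ASCII
grid format, which is plain text and round-trips exactly at the printed
precision.

The coarse grid emulates a 50-km occupancy lattice: each coarse cell owns
a ``factor`` x ``factor`` block of fine climate cells and carries a
presence flag, an optional region label and a mean elevation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Raster", "CoarseGrid", "SuitabilityMap", "VARIABLES"]

# canonical ordering of the four seasonal base variables
VARIABLES = ("t_cold", "t_warm", "p_cold", "p_warm")


@dataclass(frozen=True)
class Raster:
    """A rectangular grid of real values with planar cell-center geometry."""

    values: np.ndarray  # 2-D float array; NaN marks no-data
    cellsize: float
    xll: float = 0.0
    yll: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and self.cellsize == other.cellsize
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
        )

    def x_centers(self) -> np.ndarray:
        ncols = self.shape[1]
        return self.xll + (np.arange(ncols) + 0.5) * self.cellsize

    def y_centers(self) -> np.ndarray:
        """Cell-center y per row, row 0 northernmost (largest y)."""
        nrows = self.shape[0]
        return self.yll + (nrows - np.arange(nrows) - 0.5) * self.cellsize

    def with_values(self, values: np.ndarray) -> "Raster":
        return replace(self, values=np.asarray(values, dtype=float))

    def write_ascii(self, path: str | Path, fmt: str = "%.6f") -> None:
        out = np.where(np.isnan(self.values), self.nodata, self.values)
        nrows, ncols = self.shape
        header = (
            f"ncols {ncols}\n"
            f"nrows {nrows}\n"
            f"xllcorner {self.xll}\n"
            f"yllcorner {self.yll}\n"
            f"cellsize {self.cellsize}\n"
            f"NODATA_value {self.nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt=fmt)

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        meta: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            for _ in range(6):
                pos = fh.tell()
                line = fh.readline()
                parts = line.split()
                if len(parts) == 2 and parts[0].lower() in (
                    "ncols",
                    "nrows",
                    "xllcorner",
                    "yllcorner",
                    "cellsize",
                    "nodata_value",
                ):
                    meta[parts[0].lower()] = float(parts[1])
                else:
                    fh.seek(pos)
                    break
            values = np.loadtxt(fh).reshape(int(meta["nrows"]), int(meta["ncols"]))
        nodata = meta.get("nodata_value", -9999.0)
        values = np.where(values == nodata, np.nan, values)
        return cls(
            values=values,
            cellsize=meta["cellsize"],
            xll=meta.get("xllcorner", 0.0),
            yll=meta.get("yllcorner", 0.0),
            nodata=nodata,
        )


@dataclass
class CoarseGrid:
    """Coarse occupancy lattice over blocks of fine climate cells.

    ``presence``, ``region_id``, ``elevation`` and ``valid`` are arrays of
    shape ``(nrows, ncols)``; ``region_id`` holds ``None`` for unlabeled
    cells.  Cell ids are the row-major flat index.  ``cellsize`` is the
    coarse cell edge (km in synthetic worlds); each coarse cell owns a
    ``factor`` x ``factor`` block of fine cells.
    """

    nrows: int
    ncols: int
    cellsize: float
    factor: int
    presence: np.ndarray
    region_id: np.ndarray
    elevation: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    xll: float = 0.0
    yll: float = 0.0

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones((self.nrows, self.ncols), dtype=bool)
        for name in ("presence", "region_id", "elevation", "valid"):
            arr = getattr(self, name)
            if arr.shape != (self.nrows, self.ncols):
                raise ValueError(f"{name} shape {arr.shape} != grid shape")
        if (self.presence & ~self.valid).any():
            raise ValueError("presence flagged on a cell without valid climate")

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def fine_cellsize(self) -> float:
        return self.cellsize / self.factor

    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates per cell, flat row-major order."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xll + (cols + 0.5) * self.cellsize
        y = self.yll + (self.nrows - rows - 0.5) * self.cellsize
        xx, yy = np.meshgrid(x, y)
        return xx.ravel(), yy.ravel()

    def regions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.region_id.ravel():
            if r is not None:
                seen.setdefault(r)
        return tuple(seen)

    def region_cells(self, region: str) -> np.ndarray:
        """Flat cell ids labeled with ``region``."""
        return np.flatnonzero((self.region_id == region).ravel())

    def presence_ids(self) -> np.ndarray:
        return np.flatnonzero(self.presence.ravel())

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.unravel_index(self.cell_ids(), (self.nrows, self.ncols))
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids(),
                "row": rows,
                "col": cols,
                "presence": self.presence.ravel().astype(int),
                "region_id": [
                    r if r is not None else "" for r in self.region_id.ravel()
                ],
                "elevation_m": self.elevation.ravel(),
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, cellsize: float, factor: int
    ) -> "CoarseGrid":
        nrows = int(frame["row"].max()) + 1
        ncols = int(frame["col"].max()) + 1
        presence = np.zeros((nrows, ncols), dtype=bool)
        region = np.full((nrows, ncols), None, dtype=object)
        elev = np.full((nrows, ncols), np.nan)
        for _, r in frame.iterrows():
            i, j = int(r["row"]), int(r["col"])
            presence[i, j] = bool(int(r["presence"]))
            reg = r.get("region_id", "")
            if isinstance(reg, str) and reg:
                region[i, j] = reg
            elev[i, j] = float(r["elevation_m"])
        return cls(nrows, ncols, cellsize, factor, presence, region, elev)

    @classmethod
    def read_csv(cls, path: str | Path, cellsize: float, factor: int) -> "CoarseGrid":
        return cls.from_frame(pd.read_csv(path), cellsize, factor)


@dataclass(frozen=True)
class SuitabilityMap:
    """Ensemble occurrence probability per coarse cell for one time slice.

    ``probs`` is flat (length ``grid.n_cells``) with NaN on masked cells;
    ``ice`` flags cells forced to zero by an ice sheet; ``tag`` names the
    time slice or scenario the map belongs to.
    """

    probs: np.ndarray
    tag: str = "current"
    ice: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        finite = p[~np.isnan(p)]
        if finite.size and ((finite < 0) | (finite > 1)).any():
            raise ValueError("probabilities outside [0, 1]")
        object.__setattr__(self, "probs", p)
        if self.ice is None:
            object.__setattr__(self, "ice", np.zeros(p.shape, dtype=bool))

    @property
    def n_cells(self) -> int:
        return self.probs.size

    def masked(self) -> np.ndarray:
        return np.isnan(self.probs)

    def to_raster(self, grid: CoarseGrid) -> Raster:
        return Raster(
            values=self.probs.reshape(grid.nrows, grid.ncols),
            cellsize=grid.cellsize,
            xll=grid.xll,
            yll=grid.yll,
        )
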