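"""Raster containers and plain-text / TIFF grid I/O.

Two light-weight containers cover everything the valuation pipeline needs:
:class:`CategoricalRaster` for integer class-code maps and :class:`BandRaster`
for reflectance grids. Grids are written either as ESRI ASCII rasters
(human-readable, diff-able) or as single-band TIFFs via :mod:`tifffile`.
No georeferencing is carried beyond the square pixel edge length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "CategoricalRaster",
    "BandRaster",
    "NdviRaster",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_tiff_grid",
    "write_tiff_grid",
]


@dataclass
class CategoricalRaster:
    """A land-cover map: a 2-D grid of integer class codes with a pixel size.

    Parameters
    ----------
    grid
        2-D integer array of class codes, (row, col) indexed, row 0 at top.
    pixel_size_m
        Edge length of a (square) pixel in metres; must be positive.
    class_names
        Mapping from class code to class name. Every non-nodata code present
        in ``grid`` must be declared here.
    nodata_code
        Optional code marking cells outside the mapped area.
    """

    grid: np.ndarray
    pixel_size_m: float
    class_names: dict[int, str] = field(default_factory=dict)
    nodata_code: int | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError(f"grid must be 2-D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError(f"grid must hold integer class codes, got dtype {self.grid.dtype}")
        if self.pixel_size_m <= 0:
            raise ValueError(f"pixel_size_m must be positive, got {self.pixel_size_m}")
        present = set(np.unique(self.grid).tolist())
        if self.nodata_code is not None:
            present.discard(self.nodata_code)
        undeclared = present - set(self.class_names)
        if self.class_names and undeclared:
            raise ValueError(f"class codes {sorted(undeclared)} present in grid but not in class_names")
        if not self.class_names:
            # accept an anonymous raster; synthesize names from codes
            self.class_names = {int(c): f"class_{int(c)}" for c in sorted(present)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def pixel_area_ha(self) -> float:
        """Area of one pixel in hectares (1 ha = 10,000 m^2)."""
        return self.pixel_size_m**2 / 10_000.0

    def class_codes(self) -> list[int]:
        """Declared class codes, sorted."""
        return sorted(int(c) for c in self.class_names)

    def counts(self) -> dict[int, int]:
        """Cell count per declared class (nodata excluded)."""
        codes, counts = np.unique(self.grid, return_counts=True)
        tally = dict(zip((int(c) for c in codes), (int(n) for n in counts)))
        if self.nodata_code is not None:
            tally.pop(self.nodata_code, None)
        return {code: tally.get(code, 0) for code in self.class_codes()}


@dataclass
class BandRaster:
    """A single spectral band as a grid of finite reflectance values."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError(f"band grid must be 2-D, got shape {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("band grid contains non-finite reflectance values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class NdviRaster:
    """An NDVI grid; undefined cells (both bands zero) hold NaN."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        defined = self.grid[np.isfinite(self.grid)]
        if defined.size and (defined.min() < -1.0 - 1e-12 or defined.max() > 1.0 + 1e-12):
            raise ValueError("NDVI values outside [-1, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.grid)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(path: str | Path, grid: np.ndarray, pixel_size_m: float,
                     nodata: float | int = -9999, class_names: dict[int, str] | None = None) -> None:
    """Write a grid as an ESRI ASCII raster.

    Integer grids are written as integers, float grids at full repr precision.
    If ``class_names`` is given, a JSON sidecar ``<path>.classes.json`` records
    the code -> name legend.
    """
    path = Path(path)
    grid = np.asarray(grid)
    header = (
        f"ncols {grid.shape[1]}\n"
        f"nrows {grid.shape[0]}\n"
        "xllcorner 0.0\n"
        "yllcorner 0.0\n"
        f"cellsize {pixel_size_m}\n"
        f"NODATA_value {nodata}\n"
    )
    fmt = "%d" if np.issubdtype(grid.dtype, np.integer) else "%.10g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt=fmt)
    if class_names is not None:
        sidecar = path.with_suffix(path.suffix + ".classes.json")
        sidecar.write_text(json.dumps({str(k): v for k, v in class_names.items()}, indent=2))


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float]:
    """Read an ESRI ASCII raster; returns (grid, pixel_size_m, nodata)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    grid = np.loadtxt(lines[n_header:])
    grid = np.atleast_2d(grid)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid shape {grid.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    if np.all(grid == np.floor(grid)):
        grid = grid.astype(np.int64)
    return grid, header.get("cellsize", 1.0), header.get("nodata_value", -9999)


def write_tiff_grid(path: str | Path, grid: np.ndarray) -> None:
    """Write a grid as a single-band TIFF (no georeferencing)."""
    tifffile.imwrite(str(path), np.asarray(grid))


def read_tiff_grid(path: str | Path) -> np.ndarray:
    """Read a single-band TIFF grid."""
    return tifffile.imread(str(path))
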