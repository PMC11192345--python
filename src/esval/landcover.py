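"""Per-class area accounting and NDVI statistics for categorical rasters.

These are the quantitative primitives behind the valuation: the per-class
areas A_k (hectares) that multiply the per-hectare value coefficients, the
class shares of the mapped study area, and the normalized difference
vegetation index (NIR - red)/(NIR + red) summarized per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .rasters import BandRaster, CategoricalRaster, NdviRaster

__all__ = [
    "AreaTable",
    "ClassNdviStats",
    "compute_ndvi",
    "class_areas",
    "class_proportions",
    "ndvi_class_stats",
]

M2_PER_HA = 10_000.0


@dataclass
class AreaTable:
    """Per-class areas in hectares.

    ``total_area_ha`` defaults to (and must equal) the sum of the entries;
    the table records what the map contains, not the administrative study
    area — pass a reference total to :func:`class_proportions` when shares
    of a larger region are wanted.
    """

    entries: dict[int, float]
    total_area_ha: float | None = None
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, area in self.entries.items():
            if area < 0:
                raise ValueError(f"negative area {area} ha for class {code}")
        s = float(sum(self.entries.values()))
        if self.total_area_ha is None:
            self.total_area_ha = s
        elif s > 0 and abs(self.total_area_ha - s) > 1e-6 * s:
            raise ValueError(
                f"total_area_ha {self.total_area_ha} does not equal entry sum {s}"
            )

    def area(self, code: int) -> float:
        return self.entries[code]

    @classmethod
    def from_csv(cls, path: str | Path) -> "AreaTable":
        """Read a CSV with columns class_code, area_ha and optional class_name."""
        df = pd.read_csv(path)
        names = {}
        if "class_name" in df.columns:
            names = dict(zip(df["class_code"].astype(int), df["class_name"]))
        return cls(
            entries=dict(zip(df["class_code"].astype(int), df["area_ha"].astype(float))),
            class_names=names,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class_code": code,
                "class_name": self.class_names.get(code, f"class_{code}"),
                "area_ha": area,
            }
            for code, area in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)


class ClassNdviStats(NamedTuple):
    """Mean, population SD and defined-cell count of NDVI within one class."""

    mean: float
    sd: float
    n: int


def compute_ndvi(nir: BandRaster, red: BandRaster) -> NdviRaster:
    """Cellwise (NIR - red)/(NIR + red); cells with NIR + red = 0 are NaN.

    Both bands must be nonnegative and share a shape. Undefined cells are
    masked (NaN), never coerced to 0, so they drop out of class statistics.
    """
    if nir.shape != red.shape:
        raise ValueError(f"band shapes differ: NIR {nir.shape} vs red {red.shape}")
    if nir.grid.min() < 0 or red.grid.min() < 0:
        raise ValueError("reflectance must be nonnegative")
    denom = nir.grid + red.grid
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom > 0, (nir.grid - red.grid) / np.where(denom > 0, denom, 1.0), np.nan)
    return NdviRaster(grid=ndvi)


def class_areas(raster: CategoricalRaster) -> AreaTable:
    """Area per declared class: cell count x pixel area, in hectares.

    Nodata cells are excluded; declared classes absent from the grid appear
    with 0 ha.
    """
    px_ha = raster.pixel_area_ha
    entries = {code: n * px_ha for code, n in raster.counts().items()}
    return AreaTable(entries=entries, class_names=dict(raster.class_names))


def class_proportions(areas: AreaTable, reference_total_ha: float | None = None) -> dict[int, float]:
    """Class share of the total area.

    By default the denominator is the table's own total; pass
    ``reference_total_ha`` (e.g. the full mapped study area) to express the
    listed classes as shares of a larger region — in that case the shares of
    the listed classes need not sum to 1.
    """
    total = reference_total_ha if reference_total_ha is not None else areas.total_area_ha
    if total is None or total <= 0:
        raise ValueError("total area must be positive to compute proportions")
    return {code: area / total for code, area in areas.entries.items()}


def ndvi_class_stats(ndvi: NdviRaster, raster: CategoricalRaster) -> dict[int, ClassNdviStats]:
    """Per-class NDVI mean/SD/count over defined (non-NaN) cells.

    Classes with no defined cells are reported with ``n=0`` and NaN moments.
    """
    if ndvi.shape != raster.shape:
        raise ValueError(f"shape mismatch: NDVI {ndvi.shape} vs raster {raster.shape}")
    out: dict[int, ClassNdviStats] = {}
    defined = ndvi.defined_mask
    for code in raster.class_codes():
        sel = (raster.grid == code) & defined
        n = int(sel.sum())
        if n == 0:
            out[code] = ClassNdviStats(float("nan"), float("nan"), 0)
        else:
            vals = ndvi.grid[sel]
            out[code] = ClassNdviStats(float(vals.mean()), float(vals.std(ddof=0)), n)
    return out
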