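"""Seeded synthetic landscapes for end-to-end testing without imagery.

The generator stands in for the satellite stage: it produces (i) a
categorical land-cover raster whose class shares match prescribed target
proportions in expectation (i.i.d. multinomial cells, optionally
majority-smoothed for visual realism), (ii) a paired NIR/red reflectance
grid whose per-class NDVI matches prescribed means, and (iii) reference
points whose map labels follow a prescribed row-normalized confusion
structure. Everything is driven by a single integer seed; sub-streams are
derived deterministically, so identical spec + seed gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .accuracy import ReferencePointSet
from .rasters import BandRaster, CategoricalRaster

__all__ = [
    "ClassDef",
    "SyntheticLandscapeSpec",
    "ConfusionSpec",
    "generate_landcover",
    "generate_band_pair",
    "generate_reference_points",
    "majority_smooth",
]

#: Baseline red reflectance used when solving NIR from a target NDVI.
_RED_REFLECTANCE = 0.08
#: NDVI draws are clipped to this open interval to keep reflectances positive.
_NDVI_CLIP = 0.999


@dataclass(frozen=True)
class ClassDef:
    code: int
    name: str
    proportion: float


@dataclass
class SyntheticLandscapeSpec:
    """Recipe for a synthetic landscape.

    ``class_defs`` is an ordered list of (code, name, target proportion).
    Proportions must sum to 1; sums off by at most 1e-3 (e.g. percentages
    transcribed from a published figure that total 100.01%) are
    renormalized, anything further off is rejected. ``ndvi_targets`` maps
    class code to (mean NDVI in [-1, 1], nonnegative SD) and is only needed
    for band synthesis.
    """

    n_rows: int
    n_cols: int
    pixel_size_m: float
    class_defs: list[ClassDef]
    ndvi_targets: dict[int, tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel size must be positive")
        self.class_defs = [ClassDef(*c) if not isinstance(c, ClassDef) else c
                           for c in self.class_defs]
        if not self.class_defs:
            raise ValueError("at least one class is required")
        codes = [c.code for c in self.class_defs]
        if len(set(codes)) != len(codes):
            raise ValueError(f"class codes must be unique, got {codes}")
        s = sum(c.proportion for c in self.class_defs)
        if abs(s - 1.0) > 1e-3:
            raise ValueError(f"target proportions sum to {s!r}, not 1")
        if abs(s - 1.0) > 1e-9:
            self.class_defs = [
                ClassDef(c.code, c.name, c.proportion / s) for c in self.class_defs
            ]
        if any(c.proportion < 0 for c in self.class_defs):
            raise ValueError("target proportions must be nonnegative")
        if self.ndvi_targets is not None:
            for code, (mean, sd) in self.ndvi_targets.items():
                if not -1.0 <= mean <= 1.0:
                    raise ValueError(f"NDVI mean {mean} for class {code} outside [-1, 1]")
                if sd < 0:
                    raise ValueError(f"NDVI sd {sd} for class {code} is negative")

    @property
    def codes(self) -> list[int]:
        return [c.code for c in self.class_defs]

    @property
    def proportions(self) -> np.ndarray:
        return np.array([c.proportion for c in self.class_defs])

    @property
    def class_names(self) -> dict[int, str]:
        return {c.code: c.name for c in self.class_defs}


@dataclass
class ConfusionSpec:
    """Row-normalized label-confusion probabilities for reference-point simulation.

    Entry (i, j) is the probability that a point whose true class is
    ``classes[i]`` receives map label ``classes[j]``. Rows must sum to 1.
    The default 100 points per class reflects the usual minimum for accuracy
    assessment of large, complex maps.
    """

    classes: list[int]
    row_normalized_confusion: np.ndarray
    points_per_class: int = 100

    def __post_init__(self) -> None:
        self.row_normalized_confusion = np.asarray(self.row_normalized_confusion, dtype=float)
        k = len(self.classes)
        if self.row_normalized_confusion.shape != (k, k):
            raise ValueError(
                f"confusion shape {self.row_normalized_confusion.shape} not square of order {k}"
            )
        if (self.row_normalized_confusion < 0).any():
            raise ValueError("confusion probabilities must be nonnegative")
        sums = self.row_normalized_confusion.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValueError(
                f"confusion rows {[self.classes[i] for i in bad]} sum to "
                f"{sums[bad].tolist()}, not 1"
            )
        if self.points_per_class < 1:
            raise ValueError("points_per_class must be positive")

    @classmethod
    def from_producer_accuracy(
        cls, producer_accuracy: dict[int, float], points_per_class: int = 100
    ) -> "ConfusionSpec":
        """Diagonal = producer accuracy; off-diagonal mass spread uniformly."""
        classes = sorted(producer_accuracy)
        k = len(classes)
        mat = np.zeros((k, k))
        for i, c in enumerate(classes):
            pa = producer_accuracy[c]
            if not 0.0 <= pa <= 1.0:
                raise ValueError(f"producer accuracy {pa} for class {c} outside [0, 1]")
            mat[i, i] = pa
            if k > 1:
                mat[i, np.arange(k) != i] = (1.0 - pa) / (k - 1)
            else:
                mat[i, i] = 1.0
        return cls(classes=classes, row_normalized_confusion=mat,
                   points_per_class=points_per_class)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_landcover(spec: SyntheticLandscapeSpec, smooth: int = 0) -> CategoricalRaster:
    """Draw a land-cover raster with i.i.d. multinomial cells.

    Realized class shares converge to the targets as the grid grows (the
    per-class error is one multinomial standard error,
    sqrt(p(1-p)/n_cells)). ``smooth > 0`` applies that many majority-filter
    passes (3x3 kernel) for spatial realism; smoothing approximately
    preserves proportions but is off by default so the convergence property
    holds exactly.
    """
    rng = _rng(spec.seed, 0)
    codes = np.array(spec.codes)
    idx = rng.choice(len(codes), size=(spec.n_rows, spec.n_cols), p=spec.proportions)
    grid = codes[idx]
    for _ in range(smooth):
        grid = majority_smooth(grid, codes, size=3)
    return CategoricalRaster(
        grid=grid.astype(np.int64),
        pixel_size_m=spec.pixel_size_m,
        class_names=spec.class_names,
    )


def majority_smooth(grid: np.ndarray, codes: Sequence[int], size: int = 3) -> np.ndarray:
    """One majority-filter pass: each cell takes the modal code of its
    size x size neighbourhood (ties broken toward the lower code index)."""
    stacks = [
        ndimage.uniform_filter((grid == c).astype(float), size=size, mode="nearest")
        for c in codes
    ]
    winner = np.argmax(np.stack(stacks), axis=0)
    return np.asarray(codes)[winner]


def generate_band_pair(
    raster: CategoricalRaster, spec: SyntheticLandscapeSpec
) -> tuple[BandRaster, BandRaster]:
    """Synthesize (NIR, red) reflectance grids matching per-class NDVI targets.

    Red reflectance is held at a fixed positive baseline; per-cell NDVI is
    drawn Gaussian around the class target (clipped inside (-1, 1)) and NIR
    solved from it, so reflectances stay strictly positive and the per-class
    NDVI mean matches the target up to sampling error (exactly, for SD 0).
    """
    if spec.ndvi_targets is None:
        raise ValueError("spec.ndvi_targets is required for band synthesis")
    present = set(int(c) for c in np.unique(raster.grid))
    if raster.nodata_code is not None:
        present.discard(raster.nodata_code)
    missing = present - set(spec.ndvi_targets)
    if missing:
        raise ValueError(f"classes {sorted(missing)} have no NDVI target")

    rng = _rng(spec.seed, 1)
    ndvi = np.zeros(raster.shape, dtype=float)
    for code in sorted(present):
        mean, sd = spec.ndvi_targets[code]
        mask = raster.grid == code
        draws = rng.normal(mean, sd, size=int(mask.sum())) if sd > 0 else np.full(int(mask.sum()), float(mean))
        ndvi[mask] = np.clip(draws, -_NDVI_CLIP, _NDVI_CLIP)
    red = np.full(raster.shape, _RED_REFLECTANCE)
    nir = red * (1.0 + ndvi) / (1.0 - ndvi)
    return BandRaster(grid=nir), BandRaster(grid=red)


def generate_reference_points(
    raster: CategoricalRaster, cspec: ConfusionSpec, seed: int
) -> ReferencePointSet:
    """Sample labelled validation points with a prescribed confusion structure.

    For each class in ``cspec``, ``points_per_class`` distinct cells of that
    class are sampled and each point's map label is drawn from the class's
    confusion row. Classes with fewer cells than requested points are an
    error (shrink the point count or grow the raster).
    """
    unknown = set(cspec.classes) - set(raster.class_codes())
    if unknown:
        raise ValueError(f"confusion classes {sorted(unknown)} not in raster")
    rng = _rng(seed, 2)
    rows_out = []
    for i, code in enumerate(cspec.classes):
        r, c = np.nonzero(raster.grid == code)
        if r.size < cspec.points_per_class:
            raise ValueError(
                f"class {code} has {r.size} cells, fewer than the "
                f"{cspec.points_per_class} reference points requested"
            )
        pick = rng.choice(r.size, size=cspec.points_per_class, replace=False)
        mapped = rng.choice(
            cspec.classes, size=cspec.points_per_class,
            p=cspec.row_normalized_confusion[i],
        )
        for j, k in enumerate(pick):
            rows_out.append(
                {"row": int(r[k]), "col": int(c[k]), "true_class": code,
                 "mapped_class": int(mapped[j])}
            )
    return ReferencePointSet(records=pd.DataFrame(rows_out))
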