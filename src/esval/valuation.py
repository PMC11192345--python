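"""Benefit-transfer ecosystem-service valuation.

The model is the standard value-coefficient formulation: each land-cover
class k carries a per-hectare annual value coefficient VC_kf (USD ha^-1
yr^-1) for every service function f, and

    ESV_k = sum_f A_k * VC_kf        (value of class k)
    ESV_f = sum_k A_k * VC_kf        (value of function f)
    ESV   = sum_k sum_f A_k * VC_kf  (grand total)

with A_k the class area in hectares. Coefficients come from three routes:

* benefit transfer — a unit value from a comparable study site, scaled by an
  explicit adjustment factor (inflation or site correction);
* carbon sequestration — a per-class carbon stock (t C ha^-1) converted to
  CO2-equivalent by the molar-mass ratio 44/12 and priced at the social cost
  of carbon (USD per t CO2), entering as the climate-regulation function;
* direct market value — e.g. coffee: gross revenue (production rate x price)
  net of a cost fraction.

Missing (class, function) entries mean the service is not provided (value 0).
All arithmetic is at full precision; rounding happens only at serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .landcover import AreaTable

__all__ = [
    "CATEGORIES",
    "CO2_PER_TONNE_CARBON",
    "ServiceFunction",
    "ValueTransferRecord",
    "ServiceCoefficientTable",
    "CarbonProfile",
    "EsvReport",
    "adjust_transferred_value",
    "carbon_stock_to_co2",
    "carbon_sequestration_value",
    "coffee_npv",
    "assemble_coefficient_table",
    "esv_by_class",
    "esv_by_function",
    "esv_total",
]

#: The four Millennium-Ecosystem-Assessment service categories.
CATEGORIES = ("supporting", "regulating", "provisioning", "cultural")

#: Molar-mass ratio of CO2 to C; the exact conversion from carbon stock to
#: CO2-equivalent (the rounded 3.67 drifts at the second decimal).
CO2_PER_TONNE_CARBON = 44.0 / 12.0


@dataclass(frozen=True)
class ServiceFunction:
    """A named ecosystem-service function within one of the four categories."""

    name: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not one of {CATEGORIES}"
            )


@dataclass
class ValueTransferRecord:
    """One transferred unit value: original, adjustment factor, adjusted value.

    The adjustment factor is explicit per record (source studies differ in
    year and index); ``adjusted_value`` defaults to the exact product and,
    when supplied (e.g. transcribed from a published table), must agree with
    the product to 0.5% relative — published values are rounded.
    """

    class_code: int
    function: ServiceFunction
    original_value: float
    adjustment_factor: float
    adjusted_value: float | None = None
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.original_value < 0:
            raise ValueError(f"original value must be >= 0, got {self.original_value}")
        if self.adjustment_factor < 0:
            raise ValueError(f"adjustment factor must be >= 0, got {self.adjustment_factor}")
        exact = self.original_value * self.adjustment_factor
        if self.adjusted_value is None:
            self.adjusted_value = exact
        elif exact > 0 and abs(self.adjusted_value - exact) > 5e-3 * exact:
            raise ValueError(
                f"adjusted value {self.adjusted_value} deviates more than 0.5% from "
                f"{self.original_value} x {self.adjustment_factor} = {exact:.4f}"
            )


def adjust_transferred_value(original: float, factor: float) -> float:
    """Scale a transferred unit value by an adjustment factor (inflation etc.)."""
    if original < 0 or factor < 0:
        raise ValueError("original value and adjustment factor must be nonnegative")
    return original * factor


@dataclass
class CarbonProfile:
    """Per-class carbon stock and its valuation inputs.

    ``co2_equivalent`` defaults to stock x 44/12 and, if supplied, must match
    it within 0.01 t absolute.
    """

    class_code: int
    carbon_stock: float  # t C ha^-1
    scc: float  # USD per t CO2
    co2_equivalent: float | None = None  # t CO2 ha^-1

    def __post_init__(self) -> None:
        if self.carbon_stock < 0:
            raise ValueError(f"carbon stock must be >= 0, got {self.carbon_stock}")
        if self.scc < 0:
            raise ValueError(f"SCC must be >= 0, got {self.scc}")
        exact = carbon_stock_to_co2(self.carbon_stock)
        if self.co2_equivalent is None:
            self.co2_equivalent = exact
        elif abs(self.co2_equivalent - exact) > 0.01:
            raise ValueError(
                f"co2_equivalent {self.co2_equivalent} differs from "
                f"{self.carbon_stock} x 44/12 = {exact:.4f} by more than 0.01"
            )


def carbon_stock_to_co2(stock: float) -> float:
    """Convert a carbon stock (t C ha^-1) to CO2-equivalent (t CO2 ha^-1)."""
    if stock < 0:
        raise ValueError(f"carbon stock must be >= 0, got {stock}")
    return stock * CO2_PER_TONNE_CARBON


def carbon_sequestration_value(profile: CarbonProfile) -> float:
    """Annual sequestration value in USD ha^-1 yr^-1: CO2-equivalent x SCC."""
    return profile.co2_equivalent * profile.scc


def coffee_npv(production_rate: float, price: float, cost_fraction: float) -> float:
    """Net value of coffee production, USD ha^-1 yr^-1.

    Gross revenue is production rate (t ha^-1 yr^-1) times market price
    (USD t^-1); the net value deducts ``cost_fraction`` of gross revenue.
    """
    if production_rate < 0 or price < 0 or cost_fraction < 0:
        raise ValueError("coffee valuation inputs must be nonnegative")
    if cost_fraction > 1:
        raise ValueError(f"cost fraction must be <= 1, got {cost_fraction}")
    return production_rate * price * (1.0 - cost_fraction)


class ServiceCoefficientTable:
    """Sparse (class, function) -> USD ha^-1 yr^-1 coefficient table.

    Backed by a long-format DataFrame with columns class_code, function,
    category, value. Absent entries are zero (service not provided).
    """

    COLUMNS = ["class_code", "function", "category", "value"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"coefficient table missing columns {missing}")
        frame = frame[self.COLUMNS].copy()
        frame["class_code"] = frame["class_code"].astype(int)
        frame["value"] = frame["value"].astype(float)
        if (frame["value"] < 0).any():
            bad = frame[frame["value"] < 0]
            raise ValueError(f"negative coefficient values:\n{bad}")
        bad_cat = set(frame["category"]) - set(CATEGORIES)
        if bad_cat:
            raise ValueError(f"unknown service categories {sorted(bad_cat)}")
        dup = frame.duplicated(subset=["class_code", "function"], keep=False)
        if dup.any():
            pairs = frame.loc[dup, ["class_code", "function"]].drop_duplicates()
            raise ValueError(f"duplicate (class, function) entries: {pairs.to_dict('records')}")
        self.frame = frame.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def classes(self) -> list[int]:
        return sorted(self.frame["class_code"].unique().tolist())

    @property
    def functions(self) -> list[str]:
        return sorted(self.frame["function"].unique().tolist())

    def value(self, class_code: int, function: str) -> float:
        sel = self.frame[
            (self.frame["class_code"] == class_code) & (self.frame["function"] == function)
        ]
        return float(sel["value"].iloc[0]) if len(sel) else 0.0

    def class_vector(self, class_code: int) -> pd.Series:
        """Function -> value for one class (present entries only)."""
        sel = self.frame[self.frame["class_code"] == class_code]
        return sel.set_index("function")["value"]

    def category_subtotal(self, class_code: int, category: str) -> float:
        """Sum of a class's coefficients within one service category."""
        sel = self.frame[
            (self.frame["class_code"] == class_code) & (self.frame["category"] == category)
        ]
        return float(sel["value"].sum())

    def class_total(self, class_code: int) -> float:
        """Total per-hectare coefficient of one class across all functions."""
        return float(self.frame.loc[self.frame["class_code"] == class_code, "value"].sum())

    def perturbed(self, class_code: int, delta: float) -> "ServiceCoefficientTable":
        """A copy with every coefficient of ``class_code`` scaled by (1 + delta)."""
        frame = self.frame.copy()
        mask = frame["class_code"] == class_code
        if not mask.any():
            raise ValueError(f"class {class_code} has no coefficients to perturb")
        frame.loc[mask, "value"] *= 1.0 + delta
        return ServiceCoefficientTable(frame)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "ServiceCoefficientTable":
        df = pd.read_csv(path)
        if "value" not in df.columns and "value_usd_per_ha_yr" in df.columns:
            df = df.rename(columns={"value_usd_per_ha_yr": "value"})
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def assemble_coefficient_table(
    records: Iterable[ValueTransferRecord] = (),
    carbon: Iterable[CarbonProfile] = (),
    extra: Iterable[tuple[int, ServiceFunction, float]] = (),
) -> ServiceCoefficientTable:
    """Union benefit-transfer records, carbon valuations and direct values.

    Carbon profiles enter as the regulating-category ``climate_regulation``
    function at CO2-equivalent x SCC. Duplicate (class, function) pairs
    across the three sources are an error.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "class_code": rec.class_code,
                "function": rec.function.name,
                "category": rec.function.category,
                "value": rec.adjusted_value,
            }
        )
    for prof in carbon:
        rows.append(
            {
                "class_code": prof.class_code,
                "function": "climate_regulation",
                "category": "regulating",
                "value": carbon_sequestration_value(prof),
            }
        )
    for class_code, function, value in extra:
        rows.append(
            {
                "class_code": class_code,
                "function": function.name,
                "category": function.category,
                "value": value,
            }
        )
    frame = pd.DataFrame(rows, columns=ServiceCoefficientTable.COLUMNS)
    return ServiceCoefficientTable(frame)


@dataclass
class EsvReport:
    """Per-class, per-function, per-(class, category) and total annual values (USD yr^-1)."""

    by_class: dict[int, float]
    by_function: dict[str, float]
    by_class_category: dict[tuple[int, str], float]
    total: float

    def __post_init__(self) -> None:
        s_class = sum(self.by_class.values())
        s_func = sum(self.by_function.values())
        scale = max(abs(self.total), 1.0)
        if abs(self.total - s_class) > 1e-6 * scale or abs(self.total - s_func) > 1e-6 * scale:
            raise ValueError(
                f"inconsistent report: total {self.total}, class sum {s_class}, "
                f"function sum {s_func}"
            )

    def to_frame(self, areas: AreaTable | None = None,
                 class_names: dict[int, str] | None = None) -> pd.DataFrame:
        """Wide per-class table: per-category USD ha^-1 yr^-1 (if areas given) and
        per-category annual value in million USD."""
        names = class_names or (areas.class_names if areas is not None else {})
        rows = []
        for code in sorted(self.by_class):
            row: dict[str, object] = {
                "class_code": code,
                "class_name": names.get(code, f"class_{code}"),
            }
            if areas is not None:
                row["area_ha"] = areas.area(code)
            for cat in CATEGORIES:
                val = self.by_class_category.get((code, cat), 0.0)
                if areas is not None and areas.area(code) > 0:
                    row[f"{cat}_usd_per_ha_yr"] = val / areas.area(code)
                row[f"{cat}_million_usd"] = val / 1e6
            row["total_million_usd"] = self.by_class[code] / 1e6
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def total_million_usd(self) -> float:
        return self.total / 1e6

    @property
    def total_billion_usd(self) -> float:
        return self.total / 1e9


def _check_classes_covered(areas: AreaTable, vc: ServiceCoefficientTable) -> None:
    missing = [c for c in vc.classes if c not in areas.entries]
    if missing:
        raise ValueError(f"classes {missing} have coefficients but no area")


def esv_by_class(areas: AreaTable, vc: ServiceCoefficientTable) -> dict[int, float]:
    """ESV_k = sum_f A_k * VC_kf for every class in the coefficient table."""
    _check_classes_covered(areas, vc)
    return {
        code: areas.area(code) * vc.class_total(code)
        for code in vc.classes
    }


def esv_by_function(areas: AreaTable, vc: ServiceCoefficientTable) -> dict[str, float]:
    """ESV_f = sum_k A_k * VC_kf for every function in the coefficient table."""
    _check_classes_covered(areas, vc)
    area_col = vc.frame["class_code"].map(areas.entries)
    contrib = area_col * vc.frame["value"]
    return contrib.groupby(vc.frame["function"]).sum().to_dict()


def esv_total(areas: AreaTable, vc: ServiceCoefficientTable) -> EsvReport:
    """Full report: ESV_k, ESV_f, per-(class, category) values and the grand total."""
    _check_classes_covered(areas, vc)
    by_class = esv_by_class(areas, vc)
    by_function = esv_by_function(areas, vc)
    area_col = vc.frame["class_code"].map(areas.entries)
    contrib = (area_col * vc.frame["value"]).rename("value")
    by_cc = (
        contrib.groupby([vc.frame["class_code"], vc.frame["category"]]).sum().to_dict()
    )
    total = float(contrib.sum())
    return EsvReport(
        by_class=by_class,
        by_function=by_function,
        by_class_category={(int(k), c): float(v) for (k, c), v in by_cc.items()},
        total=total,
    )
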