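"""Loaders for the packaged study-configuration tables.

The package ships the published per-hectare coefficient table, carbon
stocks, two printed area sets, the raw value-transfer records, scalar
economic parameters, and a default synthetic-landscape recipe, all as
versioned text files under ``esval/data``.

Two area sets are printed in the source material and they disagree for
several classes; they are kept as separate fixtures: ``"carbon"`` is the
area set used in the carbon-sequestration accounting, ``"valuation"`` the
one used in the ESV accounting. The pipeline never reconciles them — the
run configuration names which one a run reproduces.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .landcover import AreaTable
from .synthetic import ConfusionSpec, SyntheticLandscapeSpec
from .valuation import CarbonProfile, ServiceCoefficientTable, ServiceFunction, ValueTransferRecord

__all__ = [
    "data_path",
    "load_parameters",
    "load_service_coefficients",
    "load_area_table",
    "load_carbon_profiles",
    "load_value_transfer_records",
    "load_landscape_spec",
    "load_confusion_spec",
]

_AREA_FILES = {"carbon": "areas_carbon.csv", "valuation": "areas_valuation.csv"}


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("esval").joinpath("data", name))


def load_parameters() -> dict:
    """Scalar economic/accounting parameters (SCC, coffee economics, study area)."""
    with open(data_path("parameters.yaml")) as fh:
        return yaml.safe_load(fh)


def load_service_coefficients() -> ServiceCoefficientTable:
    """The summary per-class x per-function coefficient table (USD ha^-1 yr^-1)."""
    return ServiceCoefficientTable.from_csv(data_path("service_coefficients.csv"))


def load_area_table(source: str = "valuation") -> AreaTable:
    """One of the two printed per-class area sets ('carbon' or 'valuation')."""
    if source not in _AREA_FILES:
        raise ValueError(f"area source must be one of {sorted(_AREA_FILES)}, got {source!r}")
    return AreaTable.from_csv(data_path(_AREA_FILES[source]))


def load_carbon_profiles(scc: float | None = None) -> list[CarbonProfile]:
    """Per-class carbon stocks priced at the social cost of carbon."""
    if scc is None:
        scc = load_parameters()["scc_usd_per_t_co2"]
    df = pd.read_csv(data_path("carbon_stocks.csv"))
    return [
        CarbonProfile(class_code=int(r.class_code), carbon_stock=float(r.carbon_stock_t_c_per_ha), scc=scc)
        for r in df.itertuples()
    ]


def load_value_transfer_records(path: str | Path | None = None) -> list[ValueTransferRecord]:
    """The raw benefit-transfer records (original value, adjusted value, source)."""
    df = pd.read_csv(path if path is not None else data_path("value_transfer.csv"))
    records = []
    for r in df.itertuples():
        original = float(r.original_value)
        adjusted = float(r.adjusted_value)
        factor = adjusted / original if original > 0 else 0.0
        records.append(
            ValueTransferRecord(
                class_code=int(r.class_code),
                function=ServiceFunction(name=str(r.function), category=str(r.category)),
                original_value=original,
                adjustment_factor=factor,
                adjusted_value=adjusted,
                source_note=str(r.source_note),
            )
        )
    return records


def _load_landscape_yaml(path: str | Path | None) -> dict:
    with open(path if path is not None else data_path("landscape.yaml")) as fh:
        return yaml.safe_load(fh)


def load_landscape_spec(seed: int = 0, path: str | Path | None = None,
                        n_rows: int | None = None, n_cols: int | None = None) -> SyntheticLandscapeSpec:
    """The default synthetic-landscape recipe (class shares + NDVI targets)."""
    cfg = _load_landscape_yaml(path)
    return SyntheticLandscapeSpec(
        n_rows=n_rows if n_rows is not None else int(cfg["n_rows"]),
        n_cols=n_cols if n_cols is not None else int(cfg["n_cols"]),
        pixel_size_m=float(cfg["pixel_size_m"]),
        class_defs=[(int(c["code"]), str(c["name"]), float(c["proportion"]))
                    for c in cfg["classes"]],
        ndvi_targets={int(c["code"]): (float(c["ndvi_mean"]), float(c["ndvi_sd"]))
                      for c in cfg["classes"]},
        seed=seed,
    )


def load_confusion_spec(path: str | Path | None = None,
                        points_per_class: int | None = None) -> ConfusionSpec:
    """The default reference-point confusion structure (producer-accuracy diagonal)."""
    cfg = _load_landscape_yaml(path)["confusion"]
    return ConfusionSpec.from_producer_accuracy(
        {int(k): float(v) for k, v in cfg["producer_accuracy"].items()},
        points_per_class=points_per_class if points_per_class is not None
        else int(cfg["points_per_class"]),
    )
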