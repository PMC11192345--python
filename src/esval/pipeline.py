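"""End-to-end run: areas -> coefficients -> valuation -> sensitivity -> report.

A :class:`RunConfig` names where the per-class areas come from (a classified
raster, a CSV, or one of the two packaged area sets), which coefficient and
carbon tables to use, and the scalar economics. :func:`run_pipeline`
validates everything up front, computes the full ESV report and per-class
sensitivity, and writes all artifacts (CSV tables plus a JSON summary) to
the output directory. Runs are deterministic: the same configuration and
seed reproduce byte-identical outputs, and every input file is logged with
its SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import datasets
from .landcover import AreaTable, class_areas, class_proportions
from .rasters import CategoricalRaster, read_ascii_grid
from .sensitivity import sensitivity_table
from .valuation import (
    CO2_PER_TONNE_CARBON,
    EsvReport,
    ServiceCoefficientTable,
    esv_total,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("esval")

_AREA_SOURCES = ("raster", "table", "carbon", "valuation")


@dataclass
class RunConfig:
    """Configuration of one valuation run.

    ``area_source`` selects exactly one area provenance: ``"raster"`` (an
    ASCII-grid land-cover map at ``raster_path``), ``"table"`` (a per-class
    area CSV at ``areas_csv``), or one of the packaged sets ``"carbon"`` /
    ``"valuation"``.
    """

    out_dir: str | Path
    area_source: str = "valuation"
    raster_path: str | Path | None = None
    areas_csv: str | Path | None = None
    coefficients_csv: str | Path | None = None  # None -> packaged table
    carbon_csv: str | Path | None = None        # None -> packaged table
    scc_usd_per_t_co2: float | None = None      # None -> packaged parameters
    study_area_ha: float | None = None          # denominator for shares
    sensitivity_delta: float = 0.5
    seed: int = 0
    report_precision: int = 2

    def __post_init__(self) -> None:
        if self.area_source not in _AREA_SOURCES:
            raise ValueError(
                f"area_source must be one of {_AREA_SOURCES}, got {self.area_source!r}"
            )
        if self.area_source == "raster" and self.raster_path is None:
            raise ValueError("area_source 'raster' requires raster_path")
        if self.area_source == "table" and self.areas_csv is None:
            raise ValueError("area_source 'table' requires areas_csv")
        for p in (self.raster_path, self.areas_csv, self.coefficients_csv, self.carbon_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _log_input(label: str, path: Path) -> None:
    log.info("input %s: %s (sha256 %s)", label, path, _sha256(path))


def _load_areas(config: RunConfig) -> AreaTable:
    if config.area_source == "raster":
        path = Path(config.raster_path)
        _log_input("raster", path)
        grid, pixel, nodata = read_ascii_grid(path)
        raster = CategoricalRaster(grid=grid, pixel_size_m=pixel, nodata_code=int(nodata))
        return class_areas(raster)
    if config.area_source == "table":
        path = Path(config.areas_csv)
        _log_input("areas", path)
        return AreaTable.from_csv(path)
    _log_input("areas", datasets.data_path(f"areas_{config.area_source}.csv"))
    return datasets.load_area_table(config.area_source)


def _round_frame(df: pd.DataFrame, ndigits: int) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(ndigits)
    return out


def run_pipeline(config: RunConfig) -> EsvReport:
    """Execute a full valuation run and write all artifacts to ``config.out_dir``.

    Artifacts: ``areas.csv``, ``coefficients.csv``, ``esv_by_class_category.csv``
    (per-class, per-category values), ``carbon_valuation.csv`` (the carbon
    chain over the carbon-accounting areas), ``sensitivity.csv``, and
    ``summary.json`` with the grand total and headline shares.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = datasets.load_parameters()
    scc = config.scc_usd_per_t_co2 if config.scc_usd_per_t_co2 is not None \
        else params["scc_usd_per_t_co2"]
    study_area = config.study_area_ha if config.study_area_ha is not None \
        else params.get("study_area_ha")
    prec = config.report_precision

    areas = _load_areas(config)
    if config.coefficients_csv is not None:
        _log_input("coefficients", Path(config.coefficients_csv))
        vc = ServiceCoefficientTable.from_csv(config.coefficients_csv)
    else:
        _log_input("coefficients", datasets.data_path("service_coefficients.csv"))
        vc = datasets.load_service_coefficients()

    missing = [c for c in vc.classes if c not in areas.entries]
    if missing:
        raise ValueError(
            f"classes {missing} appear in the coefficient table but not in the areas"
        )

    log.info("valuing %d classes x %d functions over %.2f ha",
             len(vc.classes), len(vc.functions), areas.total_area_ha)
    report = esv_total(areas, vc)

    # carbon chain over the carbon-accounting area set
    carbon = datasets.load_carbon_profiles(scc=scc) if config.carbon_csv is None else [
        # custom carbon table: same columns as the packaged one
        c for c in _custom_carbon(config.carbon_csv, scc)
    ]
    carbon_areas = areas if config.area_source != "valuation" else datasets.load_area_table("carbon")
    carbon_rows = []
    for prof in carbon:
        if prof.class_code not in carbon_areas.entries:
            continue
        per_ha = prof.co2_equivalent * prof.scc
        area = carbon_areas.area(prof.class_code)
        carbon_rows.append(
            {
                "class_code": prof.class_code,
                "class_name": carbon_areas.class_names.get(prof.class_code, ""),
                "area_ha": area,
                "carbon_stock_t_c_per_ha": prof.carbon_stock,
                "co2_equivalent_t_per_ha": prof.co2_equivalent,
                "carbon_value_usd_per_ha_yr": per_ha,
                "total_million_usd": area * per_ha / 1e6,
            }
        )
    carbon_df = pd.DataFrame(carbon_rows)

    sens = sensitivity_table(areas, vc, delta=config.sensitivity_delta, mode="per_class")
    sens_total = sensitivity_table(areas, vc, delta=config.sensitivity_delta, mode="total")
    sens_df = pd.DataFrame(
        [
            {"class_code": r.class_code, "mode": r.mode, "delta": r.delta, "cs": r.cs}
            for r in [*sens, *sens_total]
        ]
    )

    # ---- write artifacts (rounding only here) ----
    _round_frame(areas.to_frame(), prec).to_csv(out_dir / "areas.csv", index=False)
    vc.to_csv(out_dir / "coefficients.csv")
    _round_frame(report.to_frame(areas), 3).to_csv(
        out_dir / "esv_by_class_category.csv", index=False
    )
    _round_frame(carbon_df, prec).to_csv(out_dir / "carbon_valuation.csv", index=False)
    sens_df.round(6).to_csv(out_dir / "sensitivity.csv", index=False)

    shares = class_proportions(areas, reference_total_ha=study_area)
    summary = {
        "total_esv_usd_per_yr": report.total,
        "total_esv_million_usd": round(report.total_million_usd, 3),
        "total_esv_billion_usd": round(report.total_billion_usd, 3),
        "carbon_total_million_usd": round(float(carbon_df["total_million_usd"].sum()), prec)
        if len(carbon_df) else 0.0,
        "class_shares_pct": {
            str(code): round(100.0 * share, prec) for code, share in sorted(shares.items())
        },
        "by_class_million_usd": {
            str(code): round(v / 1e6, 3) for code, v in sorted(report.by_class.items())
        },
        "area_source": config.area_source,
        "scc_usd_per_t_co2": scc,
        "co2_per_tonne_carbon": CO2_PER_TONNE_CARBON,
        "seed": config.seed,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("total ESV %.3f million USD/yr -> %s", report.total_million_usd, out_dir)
    return report


def _custom_carbon(path: str | Path, scc: float):
    from .valuation import CarbonProfile

    df = pd.read_csv(path)
    for r in df.itertuples():
        yield CarbonProfile(
            class_code=int(r.class_code),
            carbon_stock=float(r.carbon_stock_t_c_per_ha),
            scc=scc,
        )
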