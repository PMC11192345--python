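import numpy as np
import pandas as pd
import pytest

from esval import datasets
from esval.landcover import AreaTable
from esval.rasters import CategoricalRaster
from esval.valuation import ServiceCoefficientTable


@pytest.fixture(scope="session")
def coefficients() -> ServiceCoefficientTable:
    return datasets.load_service_coefficients()


@pytest.fixture(scope="session")
def valuation_areas() -> AreaTable:
    return datasets.load_area_table("valuation")


@pytest.fixture(scope="session")
def carbon_areas() -> AreaTable:
    return datasets.load_area_table("carbon")


@pytest.fixture(scope="session")
def parameters() -> dict:
    return datasets.load_parameters()


@pytest.fixture
def two_class_raster() -> CategoricalRaster:
    """A 4x5 map: class 1 in the top two rows, class 2 below."""
    grid = np.array(
        [
            [1, 1, 1, 1, 1],
            [1, 1, 1, 1, 1],
            [2, 2, 2, 2, 2],
            [2, 2, 2, 2, 2],
        ]
    )
    return CategoricalRaster(
        grid=grid, pixel_size_m=100.0, class_names={1: "forest", 2: "grass"}
    )


def random_coefficient_table(rng: np.random.Generator, n_classes: int = 4,
                             n_functions: int = 5) -> ServiceCoefficientTable:
    """A dense random coefficient table for property tests."""
    from esval.valuation import CATEGORIES

    rows = []
    for k in range(1, n_classes + 1):
        for f in range(n_functions):
            rows.append(
                {
                    "class_code": k,
                    "function": f"fn_{f}",
                    "category": CATEGORIES[f % len(CATEGORIES)],
                    "value": float(rng.uniform(0, 1000)),
                }
            )
    return ServiceCoefficientTable(pd.DataFrame(rows))


def random_area_table(rng: np.random.Generator, n_classes: int = 4) -> AreaTable:
    return AreaTable(
        entries={k: float(rng.uniform(1, 1e5)) for k in range(1, n_classes + 1)}
    )
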