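"""Coefficient-of-sensitivity (elasticity) analysis.

The sensitivity coefficient CS measures how elastically the ecosystem
service value responds when one class's value coefficients are perturbed
by a fraction delta (conventionally +/-50%):

    CS = | (ESV_j - ESV_i) / ESV_i  /  ((VC_jk - VC_ik) / VC_ik) |

where i/j index the unperturbed and perturbed states. CS > 1 means elastic,
CS < 1 inelastic, CS = 1 exactly proportional.

Two readings of "ESV" are supported. In ``per_class`` mode (the default)
ESV is the perturbed class's own value: because ESV_k is linear in its
coefficients, CS is identically 1 for every class and every delta — the
perturbation propagates proportionally. In ``total`` mode ESV is the grand
total, and CS equals the class's share of total value (again independent of
delta), which ranks classes by how much the total depends on their
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .landcover import AreaTable
from .valuation import ServiceCoefficientTable, esv_total

__all__ = ["SensitivityResult", "sensitivity_coefficient", "sensitivity_table"]

Mode = Literal["per_class", "total"]


@dataclass
class SensitivityResult:
    """CS for one class under one perturbation."""

    class_code: int
    mode: Mode
    delta: float
    cs: float

    def __post_init__(self) -> None:
        if self.cs < 0:
            raise ValueError("CS is an absolute elasticity and cannot be negative")


def sensitivity_coefficient(
    areas: AreaTable,
    vc: ServiceCoefficientTable,
    target_class: int,
    delta: float = 0.5,
    mode: Mode = "per_class",
) -> SensitivityResult:
    """Elasticity of ESV with respect to a (1 + delta) scaling of one class's coefficients.

    The perturbation multiplies every service-function coefficient of
    ``target_class`` by (1 + delta), so the relative coefficient change is
    exactly ``delta`` and CS = |relative ESV change| / |delta|.
    """
    if delta == 0:
        raise ValueError("delta must be nonzero")
    if mode not in ("per_class", "total"):
        raise ValueError(f"mode must be 'per_class' or 'total', got {mode!r}")
    if target_class not in vc.classes:
        raise ValueError(f"class {target_class} has no coefficients in the table")

    base = esv_total(areas, vc)
    perturbed = esv_total(areas, vc.perturbed(target_class, delta))
    if mode == "per_class":
        esv_i = base.by_class[target_class]
        esv_j = perturbed.by_class[target_class]
    else:
        esv_i = base.total
        esv_j = perturbed.total
    if esv_i == 0:
        raise ValueError(f"baseline ESV is zero for class {target_class}; CS undefined")
    cs = abs(((esv_j - esv_i) / esv_i) / delta)
    return SensitivityResult(class_code=target_class, mode=mode, delta=delta, cs=cs)


def sensitivity_table(
    areas: AreaTable,
    vc: ServiceCoefficientTable,
    delta: float = 0.5,
    mode: Mode = "per_class",
) -> list[SensitivityResult]:
    """CS for every class in the coefficient table."""
    return [
        sensitivity_coefficient(areas, vc, code, delta=delta, mode=mode)
        for code in vc.classes
    ]
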