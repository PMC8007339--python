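"""Compounding batch arithmetic for the crushed-tablet suspension.

Per-batch and per-bottle component masses, doses per bottle, and the number
of source tablets a batch consumes.  Pure label arithmetic — no density or
reconstitution-volume modeling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import List, Sequence

from .errors import ValidationError

__all__ = [
    "FormulaComponent",
    "BatchSpec",
    "batch_total_mass",
    "doses_per_bottle",
    "tablets_required",
    "scale_batch",
]


@dataclass
class FormulaComponent:
    name: str
    function: str
    amount_g_per_batch: float

    def __post_init__(self) -> None:
        if self.amount_g_per_batch < 0:
            raise ValidationError(f"{self.name}: negative component amount")


@dataclass
class BatchSpec:
    components: List[FormulaComponent]
    n_bottles: int = 20
    bottle_volume_ml: float = 50.0
    dose_volume_ml: float = 5.0
    tablets_per_dose: int = 1
    strength_label: str = "AML 5 mg / VAL 80 mg per 5 mL"

    def __post_init__(self) -> None:
        if self.n_bottles < 1:
            raise ValidationError("need at least one bottle")
        if self.bottle_volume_ml <= 0 or self.dose_volume_ml <= 0:
            raise ValidationError("volumes must be > 0")


def batch_total_mass(spec: BatchSpec) -> tuple[float, float]:
    """(total batch mass g, per-bottle mass g)."""
    if not spec.components:
        raise ValidationError("batch has no components")
    total = sum(c.amount_g_per_batch for c in spec.components)
    return total, total / spec.n_bottles


def doses_per_bottle(bottle_volume_ml: float, dose_volume_ml: float) -> int:
    """floor(bottle / dose); warns when the division is not exact."""
    if bottle_volume_ml <= 0 or dose_volume_ml <= 0:
        raise ValidationError("volumes must be > 0")
    if dose_volume_ml > bottle_volume_ml:
        warnings.warn("dose volume exceeds bottle volume: zero doses", stacklevel=2)
        return 0
    n = math.floor(bottle_volume_ml / dose_volume_ml + 1e-9)
    if abs(bottle_volume_ml - n * dose_volume_ml) > 1e-6 * bottle_volume_ml:
        warnings.warn(
            f"bottle volume {bottle_volume_ml} mL is not an exact multiple of "
            f"the {dose_volume_ml} mL dose",
            stacklevel=2,
        )
    return n


def tablets_required(n_bottles: int, doses_per_bottle: int, tablets_per_dose: int) -> int:
    """Source tablets consumed by a batch (pure product of the counts)."""
    if min(n_bottles, doses_per_bottle, tablets_per_dose) < 1:
        raise ValidationError("all counts must be >= 1")
    return n_bottles * doses_per_bottle * tablets_per_dose


def scale_batch(spec: BatchSpec, factor: float) -> BatchSpec:
    """Linearly scale all component amounts (bottle count unchanged)."""
    if factor <= 0:
        raise ValidationError("scale factor must be > 0")
    return replace(
        spec,
        components=[
            replace(c, amount_g_per_batch=c.amount_g_per_batch * factor)
            for c in spec.components
        ],
    )
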