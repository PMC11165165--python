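"""Safe-dose extrapolation and cross-model comparability of TPD50 values.

The clinical cell-dose bound is simple multiplicative arithmetic: an anchor
dose from the mouse assay (the lowest teratoma-forming dose, or the highest
dose tested with no teratoma), divided by the PCR detection-limit fraction
for residual undifferentiated cells (a 0.001% limit contributes a factor of
1e5), and — for systemically infused products dosed per body — multiplied
by a human/mouse weight ratio.  Local routes (liver, striatum,
subcutaneous) use a weight scaling of 1.

Comparability between transplantation models (syngeneic vs allogeneic vs
xenograft) is judged on the log10 difference of TPD50 estimates against a
configurable window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._format import round_sig
from .endpoint import Td50Estimate

#: Default comparability window on |Δlog10 TPD50| (one order of magnitude).
DEFAULT_WINDOW = 1.0

ANCHOR_KINDS = ("lowest_positive", "highest_negative")

#: Default body-mass scaling for systemic (tail-vein) anchors: human/mouse
#: weight ratio of 2e3.  Local routes use 1.
WEIGHT_RATIO_HUMAN_MOUSE = 2e3


@dataclass(frozen=True)
class ThresholdInputs:
    """Inputs to the safe-dose bound.

    ``anchor_kind`` records whether the anchor is the lowest dose that formed
    a teratoma ("likelihood increases at/above the bound") or the highest
    dose with no teratoma ("no incidence observed up to the bound").
    """

    anchor_dose: float
    anchor_kind: str
    lod_fraction: float
    mass_scaling: float = 1.0

    def __post_init__(self) -> None:
        if self.anchor_dose < 1:
            raise ValueError(f"anchor_dose must be >= 1 cell, got {self.anchor_dose}")
        if self.anchor_kind not in ANCHOR_KINDS:
            raise ValueError(
                f"anchor_kind must be one of {ANCHOR_KINDS}, got {self.anchor_kind!r}"
            )
        if not 0.0 < self.lod_fraction < 1.0:
            raise ValueError(f"lod_fraction must lie in (0, 1), got {self.lod_fraction}")
        if self.mass_scaling < 1.0:
            raise ValueError(f"mass_scaling must be >= 1, got {self.mass_scaling}")


@dataclass(frozen=True)
class ThresholdResult:
    """A safe-dose bound in cells, tagged with how to phrase it."""

    cells: float
    inputs: ThresholdInputs

    @property
    def phrasing(self) -> str:
        if self.inputs.anchor_kind == "lowest_positive":
            return "teratoma likelihood increases at or above this dose"
        return "no incidence observed up to this dose in the animal model"


@dataclass(frozen=True)
class ComparabilityResult:
    """log10 TPD50 difference between two arms and the comparability verdict."""

    arm_a: str
    arm_b: str
    delta_log10: float
    window: float
    comparable: bool
    note: str = ""


def safe_dose_threshold(inputs: ThresholdInputs) -> ThresholdResult:
    """Clinical cell-dose bound: anchor × (1 / LOD fraction) × mass scaling.

    A detection limit of 0.001% (fraction 1e-5) contributes a factor of 1e5:
    a product screened clean at that sensitivity could still carry up to one
    undifferentiated cell per 1e5, so the animal anchor dose scales up by the
    reciprocal of the fraction.
    """
    cells = inputs.anchor_dose * inputs.mass_scaling / inputs.lod_fraction
    # the bound is order-of-magnitude arithmetic; strip float artifacts
    # (1e3/1e-5 = 99999999.99...) well below any meaningful precision
    return ThresholdResult(cells=round_sig(cells, 12), inputs=inputs)


def compare_td50(
    a: Td50Estimate,
    b: Td50Estimate,
    *,
    label_a: str = "arm_a",
    label_b: str = "arm_b",
    window: float = DEFAULT_WINDOW,
) -> ComparabilityResult:
    """Compare two TPD50 estimates: comparable iff |Δlog10| <= window."""
    if window <= 0:
        raise ValueError("comparability window must be positive")
    if not a.applicable or not b.applicable:
        which = label_a if not a.applicable else label_b
        return ComparabilityResult(
            arm_a=label_a,
            arm_b=label_b,
            delta_log10=math.nan,
            window=window,
            comparable=False,
            note=f"{which} has no applicable TPD50 estimate",
        )
    delta = a.log10_td50 - b.log10_td50
    return ComparabilityResult(
        arm_a=label_a,
        arm_b=label_b,
        delta_log10=delta,
        window=window,
        comparable=bool(abs(delta) <= window),
    )
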