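"""Activity arithmetic: pIC50 conversions, four-class potency binning,
signed error factors, and pharmacophore cost bookkeeping.

Activities are half-maximal inhibitory concentrations (IC50) in micromolar;
pIC50 = -log10(IC50/uM). Compounds are binned into four potency classes:

    ``++++``  most active        IC50 <= 2 uM
    ``+++``   active             2 < IC50 <= 10 uM
    ``++``    moderately active  10 < IC50 <= 20 uM
    ``+``     inactive           IC50 > 20 uM

The 2 uM boundary is taken as inclusive and the 10/20 uM boundaries as
right-closed; the tabulated compounds (e.g. 20.7 uM -> ``+``, 11 uM -> ``++``)
force the right-closed reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "pic50_from_ic50",
    "ic50_from_pic50",
    "classify_activity",
    "error_factor",
    "cost_summary",
    "CostSummary",
    "ACTIVITY_CLASSES",
]

ACTIVITY_CLASSES = ("++++", "+++", "++", "+")


def pic50_from_ic50(ic50: float) -> float:
    """Convert IC50 (uM) to pIC50 = -log10(IC50)."""
    if not ic50 > 0:
        raise ValueError(f"IC50 must be positive (uM), got {ic50!r}")
    return -math.log10(ic50)


def ic50_from_pic50(pic50: float) -> float:
    """Convert pIC50 back to IC50 in uM (exact inverse of pic50_from_ic50)."""
    return 10.0 ** (-pic50)


def classify_activity(ic50: float) -> str:
    """Four-level potency class label for an IC50 in uM."""
    if not ic50 > 0:
        raise ValueError(f"IC50 must be positive (uM), got {ic50!r}")
    if ic50 <= 2.0:
        return "++++"
    if ic50 <= 10.0:
        return "+++"
    if ic50 <= 20.0:
        return "++"
    return "+"


def error_factor(experimental: float, estimated: float) -> float:
    """Signed ratio of measured to estimated IC50.

    The larger of the two values goes in the numerator, so the magnitude is
    always >= 1. The sign is positive when the estimated IC50 is the higher
    one (the model under-predicts potency) and negative otherwise; equal
    values give +1.
    """
    if not (experimental > 0 and estimated > 0):
        raise ValueError("both IC50 values must be positive")
    hi, lo = max(experimental, estimated), min(experimental, estimated)
    magnitude = hi / lo
    return magnitude if estimated >= experimental else -magnitude


@dataclass(frozen=True)
class CostSummary:
    """Pharmacophore hypothesis costs in bits, with the reliability band
    implied by the null-minus-total cost difference."""

    fixed_cost: float
    null_cost: float
    total_cost: float
    cost_difference: float
    band: str


def cost_summary(fixed: float, null: float, total: float) -> CostSummary:
    """Summarize hypothesis costs (bits) and band the cost difference.

    A null-minus-total difference above 60 bits indicates a high (>90%)
    probability of true correlation; 40-60 bits maps to a 70-90%
    predictability band; below 40 bits the model is considered weak.
    """
    if min(fixed, null, total) < 0:
        raise ValueError("costs must be non-negative bits")
    diff = null - total
    if diff > 60.0:
        band = "high (>90%)"
    elif diff >= 40.0:
        band = "70-90%"
    else:
        band = "low"
    return CostSummary(fixed, null, total, diff, band)
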