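"""Per-drug utilization summaries: n, median/mean PDD, 95% CI, PDD/DDD.

The PDD/DDD ratio compares the mean prescribed daily dose against the
WHO defined daily dose for the presentation; a ratio strictly greater
than 1.5 is classified as excessive dosing.  The threshold is applied
to the unrounded ratio, and the inequality is strict: a drug sitting
exactly at 1.50 is not excessive.

The 95% CI is the t-interval mean +/- t(0.975, n-1) * sd / sqrt(n)
with the sample sd (ddof=1); n = 1 and zero-variance samples
degenerate to a point interval at the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

from .atc import DrugEntry, DrugRegistry
from .dosing import PatientDrugExposure

__all__ = [
    "DrugUtilizationRow",
    "EXCESSIVE_RATIO_THRESHOLD",
    "ci95",
    "is_excessive",
    "pdd_ratio",
    "round_half_up",
    "summarize_drug",
]

EXCESSIVE_RATIO_THRESHOLD = 1.5


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention; 0.725 -> 0.73).

    Goes through the decimal string so binary float artifacts
    (0.725 stored as 0.72499...) do not flip the tie direction.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def pdd_ratio(mean_pdd_mg: float, ddd_mg: float) -> float:
    """Mean PDD over DDD (unrounded; round only for display)."""
    if not ddd_mg > 0:
        raise ValueError(f"DDD must be positive, got {ddd_mg}")
    return mean_pdd_mg / ddd_mg


def is_excessive(ratio: float) -> bool:
    """Excessive dosing iff PDD/DDD > 1.5, strictly."""
    if not np.isfinite(ratio):
        raise ValueError(f"ratio must be finite, got {ratio}")
    return ratio > EXCESSIVE_RATIO_THRESHOLD


def ci95(values: Sequence[float]) -> tuple[float, float]:
    """t-based 95% confidence interval for the mean of ``values``.

    n = 1 or zero variance collapse to (mean, mean).
    """
    if len(values) == 0:
        raise ValueError("ci95 requires at least one value")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if arr.size == 1:
        return (mean, mean)
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        return (mean, mean)
    margin = float(stats.t.ppf(0.975, arr.size - 1)) * sd / np.sqrt(arr.size)
    return (mean - margin, mean + margin)


@dataclass(frozen=True)
class DrugUtilizationRow:
    """Aggregate utilization of one drug presentation across a cohort."""

    drug: DrugEntry
    n_prescriptions: int
    median_pdd_mg: float
    mean_pdd_mg: float
    ci95_mg: tuple[float, float]
    mean_pdd_over_ddd: float
    excessive: bool


def summarize_drug(
    exposures: Sequence[PatientDrugExposure],
    registry: DrugRegistry | None = None,
) -> DrugUtilizationRow:
    """Collapse per-patient exposures of one presentation into a row.

    ``n_prescriptions`` counts exposures (one per patient per
    presentation).  If a ``registry`` is given the drug is re-resolved
    through it so an unregistered drug surfaces as an unknown-drug
    error rather than a silent pass-through.
    """
    if not exposures:
        raise ValueError("summarize_drug requires at least one exposure")
    drug = exposures[0].drug
    for e in exposures[1:]:
        if e.drug.key != drug.key:
            raise ValueError("summarize_drug requires a single drug presentation")
    if registry is not None:
        drug = registry.lookup(drug.atc, drug.route, drug.form)

    pdds = np.array([e.pdd_mg_per_day for e in exposures], dtype=float)
    mean = float(pdds.mean())
    ratio = pdd_ratio(mean, drug.ddd_mg_per_day)
    return DrugUtilizationRow(
        drug=drug,
        n_prescriptions=len(exposures),
        median_pdd_mg=float(np.median(pdds)),
        mean_pdd_mg=mean,
        ci95_mg=ci95(pdds),
        mean_pdd_over_ddd=ratio,
        excessive=is_excessive(ratio),
    )
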