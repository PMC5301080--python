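"""Antipsychotic regimen classification via temporal-overlap analysis.

Antipsychotic polypharmacy (APP) is the concurrent use of two or more
antipsychotic *chemicals* by one patient.  Concurrency is resolved at
one-calendar-day granularity on the prescriptions' inclusive date
ranges; the oral and long-acting presentations of the same chemical
(identical 7-character ATC code) count as one agent.  A depot
injection is active from the injection date through its whole
interval, matching the dosing ledger.

``min_overlap_days`` (default 1) sets a cross-taper tolerance: a
concurrency level only counts if it is sustained on at least that
many days, so switching regimens with a one-day handover can be
excluded from APP by raising it to 2.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

from .atc import is_antipsychotic
from .dosing import Prescription
from .records import PatientRecord
from .utilization import round_half_up

__all__ = [
    "Regimen",
    "RegimenSummary",
    "app_share_by_drug",
    "classify_regimen",
    "concurrent_pairs",
    "max_concurrency",
]


class Regimen(str, Enum):
    NONE = "none"
    MONOTHERAPY = "monotherapy"
    POLYPHARMACY = "polypharmacy"


@dataclass(frozen=True)
class RegimenSummary:
    patient_id: str
    n_antipsychotics_total: int
    n_antipsychotics_concurrent_max: int
    regimen: Regimen
    antipsychotic_only: bool
    #: (chemical ATC a, chemical ATC b, overlap days) for each concurrent pair
    concurrent_pairs: tuple[tuple[str, str, int], ...] = ()


def _antipsychotic_filter(p: Prescription) -> bool:
    return is_antipsychotic(p.drug.atc)


def _chemical_days(
    prescriptions: Iterable[Prescription],
    keep: Callable[[Prescription], bool],
    by_presentation: bool,
) -> dict[str, set]:
    """Active calendar days per chemical (or per presentation)."""
    days: dict[str, set] = defaultdict(set)
    for p in prescriptions:
        if not keep(p):
            continue
        key = "|".join(p.drug.key) if by_presentation else p.drug.atc.code
        days[key].update(p.days())
    return days


def max_concurrency(
    prescriptions: Sequence[Prescription],
    keep: Callable[[Prescription], bool] = _antipsychotic_filter,
    min_overlap_days: int = 1,
    count_presentations_separately: bool = False,
) -> int:
    """Maximum number of distinct antipsychotic chemicals active on one day.

    With ``min_overlap_days`` k > 1, returns the highest concurrency
    level sustained on at least k (not necessarily consecutive) days.
    Prescription order never matters.
    """
    if min_overlap_days < 1:
        raise ValueError("min_overlap_days must be >= 1")
    days = _chemical_days(prescriptions, keep, count_presentations_separately)
    if not days:
        return 0
    per_day: dict = defaultdict(int)
    for day_set in days.values():
        for d in day_set:
            per_day[d] += 1
    levels = sorted(per_day.values(), reverse=True)
    best = 0
    for level in levels:
        sustained = sum(1 for v in levels if v >= level)
        if sustained >= min_overlap_days:
            best = max(best, level)
    return best


def concurrent_pairs(
    prescriptions: Sequence[Prescription],
    keep: Callable[[Prescription], bool] = _antipsychotic_filter,
    min_overlap_days: int = 1,
) -> list[tuple[str, str, int]]:
    """Chemical pairs whose active-day overlap meets the tolerance."""
    days = _chemical_days(prescriptions, keep, by_presentation=False)
    out = []
    for a, b in combinations(sorted(days), 2):
        overlap = len(days[a] & days[b])
        if overlap >= min_overlap_days:
            out.append((a, b, overlap))
    return out


def classify_regimen(patient: PatientRecord, min_overlap_days: int = 1) -> RegimenSummary:
    """None / monotherapy / polypharmacy for one patient.

    ``antipsychotic_only`` is true when the patient received at least
    one drug and every prescribed drug is an antipsychotic (mirrors
    "antipsychotics were the only psychotropic drug prescribed").
    """
    ap = patient.antipsychotic_prescriptions()
    chemicals = {p.drug.atc.code for p in ap}
    peak = max_concurrency(patient.prescriptions, min_overlap_days=min_overlap_days)
    if not chemicals:
        regimen = Regimen.NONE
    elif peak >= 2:
        regimen = Regimen.POLYPHARMACY
    else:
        regimen = Regimen.MONOTHERAPY
    return RegimenSummary(
        patient_id=patient.patient_id,
        n_antipsychotics_total=len(chemicals),
        n_antipsychotics_concurrent_max=peak,
        regimen=regimen,
        antipsychotic_only=bool(patient.prescriptions)
        and all(is_antipsychotic(p.drug.atc) for p in patient.prescriptions),
        concurrent_pairs=tuple(concurrent_pairs(ap, min_overlap_days=min_overlap_days)),
    )


def app_share_by_drug(
    patients: Sequence[PatientRecord],
    min_overlap_days: int = 1,
) -> Mapping[str, tuple[int, int, float]]:
    """Per presentation: (n users, n of them in polypharmacy, percent).

    The percent is the share of a drug's users whose overall regimen
    is antipsychotic polypharmacy, rounded to 1 decimal place; drugs
    with zero users are omitted.
    """
    users: dict[str, set] = defaultdict(set)
    poly: dict[str, set] = defaultdict(set)
    for patient in patients:
        summary = classify_regimen(patient, min_overlap_days=min_overlap_days)
        for p in patient.antipsychotic_prescriptions():
            users[p.drug.name].add(patient.patient_id)
            if summary.regimen is Regimen.POLYPHARMACY:
                poly[p.drug.name].add(patient.patient_id)
    return {
        name: (
            len(users[name]),
            len(poly[name]),
            round_half_up(100.0 * len(poly[name]) / len(users[name]), 1),
        )
        for name in sorted(users)
    }
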