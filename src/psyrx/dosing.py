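"""Daily-dose conversion and the prescribed daily dose (PDD).

A prescription is either scheduled daily (``times_per_day``) or as a
depot / long-acting injectable given every ``interval_days`` days.
The daily-dose equivalent is ``dose_mg x times_per_day`` for daily
schedules and ``dose_mg / interval_days`` for depots (calendar days,
no pharmacokinetics — e.g. 25 mg every 28 days is 0.89 mg/day).

A patient's PDD for one drug presentation is the day-by-day average of
the total daily dose over *exposed* days only (days with any nonzero
dose); overlapping orders of the same presentation sum.  Averaging
over exposed days rather than the whole admission keeps the PDD a
dose-intensity measure: it can never fall below every dose actually
prescribed.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .atc import DrugEntry, Form

__all__ = ["Prescription", "PatientDrugExposure", "daily_dose", "patient_pdd"]


@dataclass(frozen=True)
class Prescription:
    """One drug order: dose, schedule and an inclusive date range.

    Exactly one of ``times_per_day`` / ``interval_days`` is set; depot
    scheduling (``interval_days``) is only permitted for long-acting
    presentations.  A one-day order (start == end) spans one exposed
    day.
    """

    patient_id: str
    drug: DrugEntry
    dose_mg: float
    start_date: dt.date
    end_date: dt.date
    times_per_day: float | None = None
    interval_days: int | None = None

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(
                f"prescription for {self.patient_id}: start {self.start_date} "
                f"after end {self.end_date}"
            )
        if not self.dose_mg > 0:
            raise ValueError(f"dose must be positive, got {self.dose_mg}")
        if (self.times_per_day is None) == (self.interval_days is None):
            raise ValueError("exactly one of times_per_day / interval_days must be set")
        if self.times_per_day is not None and not self.times_per_day > 0:
            raise ValueError(f"times_per_day must be positive, got {self.times_per_day}")
        if self.interval_days is not None:
            if not self.interval_days >= 1:
                raise ValueError(f"interval_days must be >= 1, got {self.interval_days}")
            if self.drug.form is not Form.LONG_ACTING:
                raise ValueError(
                    f"depot schedule given for {self.drug.name!r}, which is not long-acting"
                )

    @property
    def is_depot(self) -> bool:
        return self.interval_days is not None

    def days(self) -> Iterable[dt.date]:
        """Every calendar day the order is active, inclusive both ends."""
        d = self.start_date
        while d <= self.end_date:
            yield d
            d += dt.timedelta(days=1)

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


def daily_dose(p: Prescription) -> float:
    """Daily-dose equivalent in mg/day.

    Daily schedule: dose x frequency.  Depot: dose spread uniformly
    over the injection interval (equals the mean of a per-day ledger
    that places the full dose at injection).
    """
    if p.interval_days is not None:
        return p.dose_mg / p.interval_days
    assert p.times_per_day is not None
    return p.dose_mg * p.times_per_day


@dataclass(frozen=True)
class PatientDrugExposure:
    """One patient's aggregate exposure to one drug presentation."""

    patient_id: str
    drug: DrugEntry
    pdd_mg_per_day: float
    exposed_days: int
    no_exposure: bool = False


def patient_pdd(
    prescriptions: Sequence[Prescription],
    window: tuple[dt.date, dt.date] | None = None,
) -> PatientDrugExposure:
    """PDD for one patient and one drug presentation.

    Builds a per-day ledger of total daily dose (same-presentation
    overlaps sum), optionally restricted to ``window`` (inclusive),
    and averages over the days with nonzero dose.  An empty order list
    yields a zero-PDD exposure flagged ``no_exposure`` rather than an
    exception, so cohort loops need no special-casing.
    """
    if not prescriptions:
        raise_if_window_invalid(window)
        return PatientDrugExposure(
            patient_id="", drug=None, pdd_mg_per_day=0.0, exposed_days=0, no_exposure=True
        )  # type: ignore[arg-type]
    first = prescriptions[0]
    for p in prescriptions[1:]:
        if p.patient_id != first.patient_id or p.drug.key != first.drug.key:
            raise ValueError("patient_pdd requires one patient and one drug presentation")
    raise_if_window_invalid(window)

    ledger: dict[dt.date, float] = defaultdict(float)
    for p in prescriptions:
        dd = daily_dose(p)
        for day in p.days():
            if window is not None and not (window[0] <= day <= window[1]):
                continue
            ledger[day] += dd
    exposed = [v for v in ledger.values() if v > 0]
    if not exposed:
        return PatientDrugExposure(
            patient_id=first.patient_id,
            drug=first.drug,
            pdd_mg_per_day=0.0,
            exposed_days=0,
            no_exposure=True,
        )
    return PatientDrugExposure(
        patient_id=first.patient_id,
        drug=first.drug,
        pdd_mg_per_day=sum(exposed) / len(exposed),
        exposed_days=len(exposed),
    )


def raise_if_window_invalid(window: tuple[dt.date, dt.date] | None) -> None:
    if window is not None and window[0] > window[1]:
        raise ValueError(f"empty window: {window[0]} > {window[1]}")
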