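"""Patient-level record containers shared across the analysis stages."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .dosing import Prescription

__all__ = ["Diagnosis", "PatientRecord"]


@dataclass(frozen=True)
class Diagnosis:
    """One coded diagnosis; rank 1 is the primary diagnosis."""

    icd10: str
    rank: int = 1


@dataclass
class PatientRecord:
    """Demographics, diagnoses and prescriptions for one admission.

    Diagnoses are kept in rank order (primary first, then comorbid).
    """

    patient_id: str
    age: int
    sex: str  # "F" / "M"
    admission_date: dt.date | None = None
    discharge_date: dt.date | None = None
    diagnoses: list[Diagnosis] = field(default_factory=list)
    prescriptions: list[Prescription] = field(default_factory=list)

    def antipsychotic_prescriptions(self) -> list[Prescription]:
        return [p for p in self.prescriptions if p.drug.is_antipsychotic]
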