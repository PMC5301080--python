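"""ICD-10 diagnosis grouping, age bands and off-label flagging.

Mental-and-behavioural ICD-10 codes (the F chapter) are grouped into
the decade blocks used in inpatient drug-utilization reporting:
organic (F00-F09), substance use (F10-F19), schizophrenia and other
psychoses (F20-F29), mood (F30-F39), anxiety-related (F40-F49) and
personality (F60-F69) disorders; anything else — including non-F
codes — is ``other``.

Off-label flagging is policy-driven: a delimited policy table maps
ATC prefixes to the diagnosis categories that license them.  The
shipped default licenses every antipsychotic for psychotic disorders
only; it is an editable surrogate for a regulatory label database,
not one itself.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import pandas as pd

from .atc import is_antipsychotic
from .records import PatientRecord

__all__ = [
    "AGE_BANDS",
    "DiagnosisCategory",
    "OffLabelFlag",
    "OffLabelPolicy",
    "OffLabelRationale",
    "assign_age_band",
    "categorize_icd10",
    "default_policy",
    "flag_offlabel",
]


class DiagnosisCategory(str, Enum):
    ORGANIC = "organic"
    SUBSTANCE_USE = "substance_use"
    SCHIZOPHRENIA_PSYCHOSIS = "schizophrenia_psychosis"
    MOOD = "mood"
    ANXIETY_RELATED = "anxiety_related"
    PERSONALITY = "personality"
    OTHER = "other"


# F-chapter decade -> category; decades not listed (F5x, F7x-F9x) are OTHER
_F_DECADE_CATEGORY = {
    0: DiagnosisCategory.ORGANIC,
    1: DiagnosisCategory.SUBSTANCE_USE,
    2: DiagnosisCategory.SCHIZOPHRENIA_PSYCHOSIS,
    3: DiagnosisCategory.MOOD,
    4: DiagnosisCategory.ANXIETY_RELATED,
    6: DiagnosisCategory.PERSONALITY,
}

_ICD10_RE = re.compile(r"^([A-Z])(\d{2})(?:\.?\w{1,4})?$")


def categorize_icd10(code: str) -> DiagnosisCategory:
    """Map an ICD-10 code (e.g. ``F20.0``) to its diagnosis category."""
    m = _ICD10_RE.match(code.strip().upper())
    if not m:
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    letter, digits = m.group(1), m.group(2)
    if letter != "F":
        return DiagnosisCategory.OTHER
    return _F_DECADE_CATEGORY.get(int(digits[0]), DiagnosisCategory.OTHER)


#: Half-open age bands [lo, hi); boundary ages go to the upper band.
AGE_BANDS = (
    ("18-34", 18, 35),
    ("35-49", 35, 50),
    ("50-64", 50, 65),
    ("65+", 65, None),
)


def assign_age_band(age: int) -> str:
    """Adult age band label; ages below 18 violate the inclusion criterion."""
    if age < 18:
        raise ValueError(f"age {age} below the adult inclusion criterion (>= 18)")
    for label, lo, hi in AGE_BANDS:
        if age >= lo and (hi is None or age < hi):
            return label
    raise AssertionError("unreachable")


class OffLabelRationale(str, Enum):
    PSYCHOTIC_DIAGNOSIS = "psychotic_diagnosis"
    APPROVED_NONPSYCHOTIC = "approved_nonpsychotic"
    NO_ELIGIBLE_DIAGNOSIS = "no_eligible_diagnosis"


@dataclass(frozen=True)
class OffLabelFlag:
    patient_id: str
    drug_name: str
    atc: str
    on_label: bool
    rationale: OffLabelRationale


class OffLabelPolicy:
    """ATC-prefix -> licensed diagnosis categories.

    A drug's licensed set is the union over every policy row whose
    prefix matches its ATC code, which makes the off-label share
    monotone nonincreasing as allowed sets grow.
    """

    def __init__(self, rows: list[tuple[str, frozenset[DiagnosisCategory]]]) -> None:
        self.rows = [(prefix.upper(), cats) for prefix, cats in rows]

    def allowed_categories(self, atc_code: str) -> frozenset[DiagnosisCategory] | None:
        """None when no policy row covers the drug at all."""
        matched = [cats for prefix, cats in self.rows if atc_code.upper().startswith(prefix)]
        if not matched:
            return None
        return frozenset().union(*matched)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OffLabelPolicy":
        rows = []
        for _, row in df.iterrows():
            cats = frozenset(
                DiagnosisCategory(c.strip())
                for c in str(row["allowed_categories"]).split(";")
                if c.strip()
            )
            rows.append((str(row["atc_prefix"]), cats))
        return cls(rows)

    @classmethod
    def from_csv(cls, path) -> "OffLabelPolicy":
        return cls.from_frame(pd.read_csv(path, sep=None, engine="python", encoding="utf-8"))


def default_policy() -> OffLabelPolicy:
    with resources.files("psyrx.data").joinpath("default_policy.csv").open("rb") as fh:
        return OffLabelPolicy.from_csv(fh)


def flag_offlabel(
    patient: PatientRecord, policy: OffLabelPolicy | None = None
) -> list[OffLabelFlag]:
    """One flag per antipsychotic presentation the patient received.

    On-label when any of the patient's diagnosis categories is in the
    policy's licensed set for the drug; a drug no policy row covers is
    flagged ``no_eligible_diagnosis`` with a warning rather than an
    exception.
    """
    policy = policy or default_policy()
    categories = {categorize_icd10(d.icd10) for d in patient.diagnoses}
    flags: list[OffLabelFlag] = []
    seen: set[tuple[str, str, str]] = set()
    for p in patient.prescriptions:
        if not is_antipsychotic(p.drug.atc) or p.drug.key in seen:
            continue
        seen.add(p.drug.key)
        allowed = policy.allowed_categories(p.drug.atc.code)
        if allowed is None:
            warnings.warn(
                f"no off-label policy row covers {p.drug.name} ({p.drug.atc}); "
                "flagging as no eligible diagnosis",
                stacklevel=2,
            )
            on, why = False, OffLabelRationale.NO_ELIGIBLE_DIAGNOSIS
        elif DiagnosisCategory.SCHIZOPHRENIA_PSYCHOSIS in categories & allowed:
            on, why = True, OffLabelRationale.PSYCHOTIC_DIAGNOSIS
        elif categories & allowed:
            on, why = True, OffLabelRationale.APPROVED_NONPSYCHOTIC
        else:
            on, why = False, OffLabelRationale.NO_ELIGIBLE_DIAGNOSIS
        flags.append(
            OffLabelFlag(
                patient_id=patient.patient_id,
                drug_name=p.drug.name,
                atc=p.drug.atc.code,
                on_label=on,
                rationale=why,
            )
        )
    return flags
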