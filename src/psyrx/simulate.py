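"""Seeded synthetic inpatient cohorts for end-to-end testing.

Two kinds of synthetic data:

* :func:`generate` draws a randomized brief-inpatient cohort from a
  :class:`CohortSpec` — diagnosis-category mix, age/sex distribution,
  per-category antipsychotic use probability, monotherapy vs
  polypharmacy split, and per-drug lognormal daily doses centered on
  a target PDD/DDD multiple of the registry DDD.  Same seed, same
  bytes.  The emitted tables are exactly the formats the readers
  consume, so the generator doubles as the integration-test driver.
  Default parameters mirror a published Spanish brief-inpatient
  cohort (353 patients, 61.5% antipsychotic users, 36.8% of users on
  polypharmacy).

* :func:`fixture_table3_cohort` and :func:`fixture_table2_cohort` are
  hand-constructed deterministic mini-cohorts that reproduce the
  bundled reference tables' per-drug n / median / mean PDD rows and
  the diagnosis-by-regimen counts exactly.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .atc import DrugEntry, DrugRegistry, Form, Route, default_registry, parse_atc
from .diagnoses import DiagnosisCategory
from .io import reference_regimens, reference_utilization

__all__ = [
    "CohortSpec",
    "extended_registry",
    "fixture_table2_cohort",
    "fixture_table3_cohort",
    "generate",
]

_BASE_DATE = dt.date(2014, 6, 1)  # cohort window opens here

#: Representative ICD-10 code per category for generated diagnoses.
_CATEGORY_CODE = {
    DiagnosisCategory.ORGANIC: "F00",
    DiagnosisCategory.SUBSTANCE_USE: "F10.2",
    DiagnosisCategory.SCHIZOPHRENIA_PSYCHOSIS: "F20.0",
    DiagnosisCategory.MOOD: "F32.1",
    DiagnosisCategory.ANXIETY_RELATED: "F41.1",
    DiagnosisCategory.PERSONALITY: "F60.3",
    DiagnosisCategory.OTHER: "F99",
}

#: Non-antipsychotic psychotropics the generator may co-prescribe.
_OTHER_PSYCHOTROPICS = [
    ("N05BA01", "Diazepam", 10.0),
    ("N06AB06", "Sertraline", 50.0),
    ("N03AG01", "Valproic acid", 1500.0),
]


def extended_registry() -> DrugRegistry:
    """Default antipsychotic registry plus the co-prescribed psychotropics."""
    reg = default_registry()
    for atc, name, ddd in _OTHER_PSYCHOTROPICS:
        reg.add(
            DrugEntry(
                atc=parse_atc(atc),
                name=name,
                route=Route.ORAL,
                form=Form.STANDARD,
                ddd_mg_per_day=ddd,
            )
        )
    return reg


def _default_category_weights() -> dict[DiagnosisCategory, float]:
    # single-diagnosis mix of the emulated cohort (243 single-diagnosis patients)
    raw = {
        DiagnosisCategory.SUBSTANCE_USE: 16,
        DiagnosisCategory.SCHIZOPHRENIA_PSYCHOSIS: 101,
        DiagnosisCategory.MOOD: 69,
        DiagnosisCategory.ANXIETY_RELATED: 24,
        DiagnosisCategory.PERSONALITY: 21,
        DiagnosisCategory.OTHER: 12,
    }
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def _default_use_probs() -> dict[DiagnosisCategory, float]:
    # per-category antipsychotic use among single-diagnosis patients
    return {
        DiagnosisCategory.ORGANIC: 0.4,
        DiagnosisCategory.SUBSTANCE_USE: 8 / 16,
        DiagnosisCategory.SCHIZOPHRENIA_PSYCHOSIS: 1.0,
        DiagnosisCategory.MOOD: 51 / 69,
        DiagnosisCategory.ANXIETY_RELATED: 5 / 24,
        DiagnosisCategory.PERSONALITY: 12 / 21,
        DiagnosisCategory.OTHER: 0.0,
    }


def _default_mean_ratios() -> dict[str, float]:
    ref = reference_utilization()
    return {row.drug: float(row.ratio) for row in ref.itertuples(index=False)}


def _default_drug_weights() -> dict[str, float]:
    ref = reference_utilization()
    total = float(ref["n"].sum())
    return {row.drug: row.n / total for row in ref.itertuples(index=False)}


class CohortSpec(BaseModel):
    """Generator parameters; defaults emulate a brief-inpatient unit."""

    n_patients: int = Field(default=353, gt=0)
    category_weights: dict[DiagnosisCategory, float] = Field(
        default_factory=_default_category_weights
    )
    comorbidity_prob: float = Field(default=110 / 353, ge=0, le=1)
    antipsychotic_use_prob_by_category: dict[DiagnosisCategory, float] = Field(
        default_factory=_default_use_probs
    )
    polypharmacy_prob: float = Field(default=80 / 217, ge=0, le=1)
    other_psychotropic_prob: float = Field(default=0.7, ge=0, le=1)
    dose_lognormal_sigma: float = Field(default=0.4, gt=0)
    mean_ratio_by_drug: dict[str, float] = Field(default_factory=_default_mean_ratios)
    drug_weights: dict[str, float] = Field(default_factory=_default_drug_weights)
    age_band_weights: tuple[float, float, float, float] = (0.273, 0.355, 0.273, 0.099)
    female_prob: float = Field(default=0.487, ge=0, le=1)
    stay_days: tuple[int, int] = (7, 30)

    @field_validator("category_weights", "drug_weights")
    @classmethod
    def _weights_sum_to_one(cls, v):
        total = sum(v.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"weights must sum to 1, got {total}")
        if any(w < 0 for w in v.values()):
            raise ValueError("weights must be nonnegative")
        return v

    @field_validator("antipsychotic_use_prob_by_category")
    @classmethod
    def _probs_in_unit_interval(cls, v):
        if any(not (0 <= p <= 1) for p in v.values()):
            raise ValueError("use probabilities must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _stay_range_valid(self):
        lo, hi = self.stay_days
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid stay_days range {self.stay_days}")
        return self

    @classmethod
    def uniform_use(cls, use_prob: float, **kwargs) -> "CohortSpec":
        """Spec with one flat antipsychotic-use probability everywhere."""
        probs = {cat: use_prob for cat in DiagnosisCategory}
        return cls(antipsychotic_use_prob_by_category=probs, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))


def _draw_age(rng: np.random.Generator, weights) -> int:
    band = rng.choice(4, p=np.asarray(weights) / np.sum(weights))
    edges = [(18, 34), (35, 49), (50, 64), (65, 90)]
    lo, hi = edges[band]
    return int(rng.integers(lo, hi + 1))


def _draw_dose_mg_per_day(
    rng: np.random.Generator, ddd: float, ratio: float, sigma: float
) -> float:
    """Lognormal daily dose with mean ratio * DDD."""
    mu = np.log(ratio * ddd) - sigma**2 / 2
    return float(np.exp(rng.normal(mu, sigma)))


def generate(
    spec: CohortSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; returns (patients, diagnoses, prescriptions).

    Deterministic given ``seed``.  Each patient receives 1–2 diagnosis
    categories, and with the primary category's use probability one
    antipsychotic — or, with
    ``polypharmacy_prob``, two chemically distinct antipsychotics with
    overlapping date ranges.  Doses are lognormal around the drug's
    target PDD/DDD multiple of its DDD; depot presentations are dosed
    every 28 days.
    """
    rng = np.random.default_rng(seed)
    registry = extended_registry()
    cats = list(spec.category_weights)
    cat_p = np.array([spec.category_weights[c] for c in cats], dtype=float)
    cat_p = cat_p / cat_p.sum()
    drugs = list(spec.drug_weights)
    drug_p = np.array([spec.drug_weights[d] for d in drugs], dtype=float)
    drug_p = drug_p / drug_p.sum()

    patients, diagnoses, prescriptions = [], [], []
    for i in range(spec.n_patients):
        pid = f"P{i + 1:05d}"
        admission = _BASE_DATE + dt.timedelta(days=int(rng.integers(0, 120)))
        stay = int(rng.integers(spec.stay_days[0], spec.stay_days[1] + 1))
        discharge = admission + dt.timedelta(days=stay - 1)
        patients.append(
            {
                "patient_id": pid,
                "age": _draw_age(rng, spec.age_band_weights),
                "sex": "F" if rng.random() < spec.female_prob else "M",
                "admission_date": admission.isoformat(),
                "discharge_date": discharge.isoformat(),
            }
        )

        my_cats = [cats[rng.choice(len(cats), p=cat_p)]]
        if rng.random() < spec.comorbidity_prob:
            second = cats[rng.choice(len(cats), p=cat_p)]
            if second != my_cats[0]:
                my_cats.append(second)
        for rank, cat in enumerate(my_cats, start=1):
            diagnoses.append(
                {"patient_id": pid, "icd10": _CATEGORY_CODE[cat], "rank": rank}
            )

        # use probability follows the primary (first-ranked) diagnosis
        use_p = spec.antipsychotic_use_prob_by_category.get(my_cats[0], 0.0)
        if rng.random() >= use_p:
            continue

        n_ap = 1
        if rng.random() < spec.polypharmacy_prob:
            n_ap = 2
        chosen: list[str] = []
        chemicals: set[str] = set()
        while len(chosen) < n_ap:
            name = drugs[rng.choice(len(drugs), p=drug_p)]
            entry = registry.lookup_by_name(name)
            if entry.atc.code in chemicals:
                continue
            chosen.append(name)
            chemicals.add(entry.atc.code)
        for j, name in enumerate(chosen):
            entry = registry.lookup_by_name(name)
            daily = _draw_dose_mg_per_day(
                rng,
                entry.ddd_mg_per_day,
                spec.mean_ratio_by_drug.get(name, 1.0),
                spec.dose_lognormal_sigma,
            )
            # second agent starts mid-stay but always overlaps the first
            start_off = 0 if j == 0 else int(rng.integers(0, max(1, stay - 1)))
            start = admission + dt.timedelta(days=start_off)
            row = {
                "patient_id": pid,
                "drug": name,
                "atc": entry.atc.code,
                "route": entry.route.value,
                "form": entry.form.value,
                "start_date": start.isoformat(),
                "end_date": discharge.isoformat(),
            }
            if entry.form is Form.LONG_ACTING:
                row |= {"dose_mg": round(daily * 28, 3), "times_per_day": "", "interval_days": 28}
            else:
                row |= {"dose_mg": round(daily, 3), "times_per_day": 1, "interval_days": ""}
            prescriptions.append(row)

        if rng.random() < spec.other_psychotropic_prob:
            atc, name, ddd = _OTHER_PSYCHOTROPICS[
                rng.choice(len(_OTHER_PSYCHOTROPICS))
            ]
            prescriptions.append(
                {
                    "patient_id": pid,
                    "drug": name,
                    "atc": atc,
                    "route": "oral",
                    "form": "standard",
                    "start_date": admission.isoformat(),
                    "end_date": discharge.isoformat(),
                    "dose_mg": ddd,
                    "times_per_day": 1,
                    "interval_days": "",
                }
            )

    rx_cols = [
        "patient_id", "drug", "atc", "dose_mg", "route", "form",
        "times_per_day", "interval_days", "start_date", "end_date",
    ]
    return (
        pd.DataFrame(patients),
        pd.DataFrame(diagnoses),
        pd.DataFrame(prescriptions, columns=rx_cols),
    )


def _reconstruct_pdds(n: int, median: float, mean: float) -> list[float]:
    """A positive sample of size n with the given median and mean.

    Keeps the middle order statistic(s) at the median and shifts the
    top (mean > median) or bottom (mean < median) tail to hit the
    mean exactly.
    """
    if n == 1:
        return [mean]
    if np.isclose(mean, median):
        return [median] * n
    k = (n - 1) // 2 if n % 2 == 1 else n // 2 - 1
    if k == 0:
        raise ValueError(f"cannot reconcile n={n} with median {median} != mean {mean}")
    tail = (n * mean - (n - k) * median) / k
    if mean > median:
        values = [median] * (n - k) + [tail] * k
    else:
        if tail <= 0:
            raise ValueError("reconstruction would need nonpositive doses")
        values = [tail] * k + [median] * (n - k)
    return values


def fixture_table3_cohort() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Deterministic cohort reproducing the reference utilization rows.

    One patient per exposure (365 patients); each drug's exposure
    PDDs are reconstructed to match the reference n, median and mean
    exactly, so the analyzer's Table 3 reproduces those columns and
    every PDD/DDD ratio.  Synthetic: stands in for the unpublished
    patient-level data behind the reference table.
    """
    registry = default_registry()
    ref = reference_utilization()
    patients, diagnoses, prescriptions = [], [], []
    pid_counter = 0
    admission = _BASE_DATE
    discharge = admission + dt.timedelta(days=27)  # 28-day window
    for row in ref.itertuples(index=False):
        entry = registry.lookup_by_name(row.drug)
        for pdd in _reconstruct_pdds(int(row.n), float(row.median_pdd), float(row.mean_pdd)):
            pid_counter += 1
            pid = f"T3-{pid_counter:03d}"
            patients.append(
                {
                    "patient_id": pid,
                    "age": 30 + (pid_counter % 40),
                    "sex": "F" if pid_counter % 2 else "M",
                    "admission_date": admission.isoformat(),
                    "discharge_date": discharge.isoformat(),
                }
            )
            diagnoses.append({"patient_id": pid, "icd10": "F20.0", "rank": 1})
            rx = {
                "patient_id": pid,
                "drug": row.drug,
                "atc": row.atc,
                "route": row.route,
                "form": row.form,
                "start_date": admission.isoformat(),
                "end_date": discharge.isoformat(),
            }
            if Form(row.form) is Form.LONG_ACTING:
                rx |= {"dose_mg": pdd * 28, "times_per_day": "", "interval_days": 28}
            else:
                rx |= {"dose_mg": pdd, "times_per_day": 1, "interval_days": ""}
            prescriptions.append(rx)
    rx_cols = [
        "patient_id", "drug", "atc", "dose_mg", "route", "form",
        "times_per_day", "interval_days", "start_date", "end_date",
    ]
    return (
        pd.DataFrame(patients),
        pd.DataFrame(diagnoses),
        pd.DataFrame(prescriptions, columns=rx_cols),
    )


_STRATUM_CODES = {
    "substance_use": ["F10.2"],
    "schizophrenia_psychosis": ["F20.0"],
    "mood": ["F32.1"],
    "anxiety_related": ["F41.1"],
    "personality": ["F60.3"],
    "other": ["F99"],
    "organic;mood": ["F00", "F32.1"],
    "substance_use;schizophrenia_psychosis": ["F10.2", "F20.0"],
    "substance_use;mood": ["F10.2", "F32.1"],
    "substance_use;personality": ["F10.2", "F60.3"],
    "schizophrenia_psychosis;personality": ["F20.0", "F60.3"],
    "mood;personality": ["F32.1", "F60.3"],
    "anxiety_related;personality": ["F41.1", "F60.3"],
    "other_combinations": ["F10.2", "F20.0", "F32.1"],
}


def fixture_table2_cohort() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Deterministic cohort reproducing the diagnosis-by-regimen counts.

    Synthetic reconstruction: per reference stratum it creates the
    printed number of monotherapy users (one antipsychotic),
    polypharmacy users (two overlapping antipsychotics) and non-users.
    One reference stratum prints more users than patients (9 vs 7);
    that stratum gets max(n, users) patients so the user columns and
    totals are preserved.
    """
    ref = reference_regimens()
    patients, diagnoses, prescriptions = [], [], []
    pid_counter = 0
    admission = _BASE_DATE
    discharge = admission + dt.timedelta(days=13)
    for row in ref.itertuples(index=False):
        codes = _STRATUM_CODES[row.categories]
        total = max(int(row.n), int(row.users))
        for i in range(total):
            pid_counter += 1
            pid = f"T2-{pid_counter:03d}"
            patients.append(
                {
                    "patient_id": pid,
                    "age": 25 + (pid_counter % 50),
                    "sex": "F" if pid_counter % 2 else "M",
                    "admission_date": admission.isoformat(),
                    "discharge_date": discharge.isoformat(),
                }
            )
            for rank, code in enumerate(codes, start=1):
                diagnoses.append({"patient_id": pid, "icd10": code, "rank": rank})
            if i < int(row.mono):
                drug_names = ["Risperidone"]
            elif i < int(row.users):
                drug_names = ["Risperidone", "Olanzapine"]
            else:
                drug_names = []
            for name, dose in zip(drug_names, (6.0, 10.0)):
                prescriptions.append(
                    {
                        "patient_id": pid,
                        "drug": name,
                        "atc": "",
                        "dose_mg": dose,
                        "route": "oral",
                        "form": "standard",
                        "times_per_day": 1,
                        "interval_days": "",
                        "start_date": admission.isoformat(),
                        "end_date": discharge.isoformat(),
                    }
                )
    rx_cols = [
        "patient_id", "drug", "atc", "dose_mg", "route", "form",
        "times_per_day", "interval_days", "start_date", "end_date",
    ]
    return (
        pd.DataFrame(patients),
        pd.DataFrame(diagnoses),
        pd.DataFrame(prescriptions, columns=rx_cols),
    )
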