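"""Cohort-level reports: the three utilization tables and headline rates.

* Table 1 — demographics: per diagnosis category, patient counts, the
  within-category age-band and sex distributions, and Pearson
  chi-square independence P values (category-vs-rest against band or
  sex, without continuity correction).
* Table 2 — diagnosis strata (single categories, named comorbidity
  pairs, catch-alls) cross-tabulated against antipsychotic use and
  regimen (monotherapy / polypharmacy), with a totals row.
* Table 3 — per-presentation drug utilization rows (n, median/mean
  PDD, 95% CI, mean PDD/DDD, excessive-dose flag).

All numbers are computed unrounded and rounded only at serialization
(half away from zero; percentages to 1 dp, doses and ratios to 2 dp).
"""

from __future__ import annotations

import json
import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .atc import DrugRegistry, default_registry
from .diagnoses import (
    AGE_BANDS,
    DiagnosisCategory,
    OffLabelPolicy,
    assign_age_band,
    categorize_icd10,
    default_policy,
    flag_offlabel,
)
from .dosing import PatientDrugExposure, patient_pdd
from .records import PatientRecord
from .regimen import Regimen, classify_regimen
from .utilization import DrugUtilizationRow, round_half_up, summarize_drug

__all__ = [
    "CohortReport",
    "analyze_cohort",
    "build_table1",
    "build_table2",
    "build_table3",
    "cohort_exposures",
    "percent",
    "write_report",
]

#: Sentinel for a percentage with zero denominator.
UNDEFINED_PERCENT = float("nan")

_CATEGORY_LABELS = {
    DiagnosisCategory.ORGANIC: "Organic disorders",
    DiagnosisCategory.SUBSTANCE_USE: "Substance use disorders",
    DiagnosisCategory.SCHIZOPHRENIA_PSYCHOSIS: "Schizophrenia and other psychoses",
    DiagnosisCategory.MOOD: "Mood disorders",
    DiagnosisCategory.ANXIETY_RELATED: "Anxiety-related disorders",
    DiagnosisCategory.PERSONALITY: "Personality disorders",
    DiagnosisCategory.OTHER: "Other disorders",
}

_TABLE1_ORDER = [
    DiagnosisCategory.SUBSTANCE_USE,
    DiagnosisCategory.SCHIZOPHRENIA_PSYCHOSIS,
    DiagnosisCategory.MOOD,
    DiagnosisCategory.ANXIETY_RELATED,
    DiagnosisCategory.PERSONALITY,
    DiagnosisCategory.ORGANIC,
    DiagnosisCategory.OTHER,
]

#: Single-category strata that get a named Table 2 row.
_NAMED_SINGLES = [
    DiagnosisCategory.SUBSTANCE_USE,
    DiagnosisCategory.SCHIZOPHRENIA_PSYCHOSIS,
    DiagnosisCategory.MOOD,
    DiagnosisCategory.ANXIETY_RELATED,
    DiagnosisCategory.PERSONALITY,
]

#: Named comorbidity pairs, keyed by unordered category pair.
_NAMED_PAIRS: list[tuple[frozenset, str]] = [
    (
        frozenset({DiagnosisCategory.ORGANIC, DiagnosisCategory.MOOD}),
        "Organic disorders + mood disorders",
    ),
    (
        frozenset({DiagnosisCategory.SUBSTANCE_USE, DiagnosisCategory.SCHIZOPHRENIA_PSYCHOSIS}),
        "Substance use disorders + schizophrenia and other psychosis",
    ),
    (
        frozenset({DiagnosisCategory.SUBSTANCE_USE, DiagnosisCategory.MOOD}),
        "Substance use disorders + mood disorders",
    ),
    (
        frozenset({DiagnosisCategory.SUBSTANCE_USE, DiagnosisCategory.PERSONALITY}),
        "Substance use disorders + personality disorders",
    ),
    (
        frozenset({DiagnosisCategory.SCHIZOPHRENIA_PSYCHOSIS, DiagnosisCategory.PERSONALITY}),
        "Schizophrenia and other psychosis + personality disorders",
    ),
    (
        frozenset({DiagnosisCategory.MOOD, DiagnosisCategory.PERSONALITY}),
        "Mood disorders + personality disorders",
    ),
    (
        frozenset({DiagnosisCategory.ANXIETY_RELATED, DiagnosisCategory.PERSONALITY}),
        "Anxiety-related disorders + personality disorders",
    ),
]

REST_OF_DIAGNOSES = "Rest of the diagnoses"
OTHER_COMBINATIONS = "Other combinations"


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """100 * num / den, rounded half away from zero; NaN when den == 0."""
    if denominator == 0:
        return UNDEFINED_PERCENT
    return round_half_up(100.0 * numerator / denominator, ndigits)


def patient_categories(patient: PatientRecord) -> set[DiagnosisCategory]:
    return {categorize_icd10(d.icd10) for d in patient.diagnoses}


def table2_stratum(patient: PatientRecord) -> str:
    """Assign a patient to exactly one Table 2 stratum."""
    cats = patient_categories(patient)
    if len(cats) == 1:
        (cat,) = cats
        if cat in _NAMED_SINGLES:
            return _CATEGORY_LABELS[cat].replace("psychoses", "psychosis")
        return REST_OF_DIAGNOSES
    if len(cats) == 2:
        for pair, label in _NAMED_PAIRS:
            if cats == pair:
                return label
    return OTHER_COMBINATIONS


def _chi2_p(table: np.ndarray) -> float:
    """Pearson chi-square P without continuity correction; NaN if degenerate."""
    table = table[:, table.sum(axis=0) > 0]
    table = table[table.sum(axis=1) > 0, :]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return float("nan")
    res = chi2_contingency(table, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("chi-square expected counts below 5; P value is approximate", stacklevel=3)
    return float(res.pvalue)


def build_table1(
    patients: Sequence[PatientRecord],
    p_value_mode: Literal["category_vs_rest", "full_table"] = "category_vs_rest",
) -> pd.DataFrame:
    """Demographics-by-diagnosis table with chi-square P values.

    A patient with comorbid diagnoses contributes one row-membership
    per named category.  ``category_vs_rest`` tests each category's
    members against the rest of the cohort (independently for age
    band and sex); ``full_table`` reuses the full category-by-band
    (or -sex) contingency P for every row.
    """
    n_total = len(patients)
    band_labels = [b[0] for b in AGE_BANDS]
    members = {
        cat: [p for p in patients if cat in patient_categories(p)] for cat in _TABLE1_ORDER
    }

    def band_counts(group: Sequence[PatientRecord]) -> np.ndarray:
        c = {b: 0 for b in band_labels}
        for p in group:
            c[assign_age_band(p.age)] += 1
        return np.array([c[b] for b in band_labels])

    def sex_counts(group: Sequence[PatientRecord]) -> np.ndarray:
        return np.array(
            [sum(1 for p in group if p.sex == "F"), sum(1 for p in group if p.sex == "M")]
        )

    full_age = np.array([band_counts(members[c]) for c in _TABLE1_ORDER if members[c]])
    full_sex = np.array([sex_counts(members[c]) for c in _TABLE1_ORDER if members[c]])
    p_age_full = _chi2_p(full_age) if len(full_age) else float("nan")
    p_sex_full = _chi2_p(full_sex) if len(full_sex) else float("nan")

    rows = []
    for cat in _TABLE1_ORDER:
        group = members[cat]
        if not group:
            continue
        rest = [p for p in patients if cat not in patient_categories(p)]
        n = len(group)
        bands = band_counts(group)
        sexes = sex_counts(group)
        if p_value_mode == "category_vs_rest":
            p_age = _chi2_p(np.vstack([bands, band_counts(rest)])) if rest else float("nan")
            p_sex = _chi2_p(np.vstack([sexes, sex_counts(rest)])) if rest else float("nan")
        else:
            p_age, p_sex = p_age_full, p_sex_full
        rows.append(
            {
                "category": _CATEGORY_LABELS[cat],
                "n": n,
                "pct_of_cohort": percent(n, n_total),
                **{f"age_{b}_pct": percent(k, n) for b, k in zip(band_labels, bands)},
                "p_age": p_age,
                "female_pct": percent(sexes[0], n),
                "male_pct": percent(sexes[1], n),
                "p_sex": p_sex,
            }
        )
    # cohort-wide totals row
    bands = band_counts(patients)
    sexes = sex_counts(patients)
    rows.append(
        {
            "category": f"Total (N={n_total})",
            "n": n_total,
            "pct_of_cohort": percent(n_total, n_total) if n_total else UNDEFINED_PERCENT,
            **{f"age_{b}_pct": percent(k, n_total) for b, k in zip(band_labels, bands)},
            "p_age": float("nan"),
            "female_pct": percent(sexes[0], n_total),
            "male_pct": percent(sexes[1], n_total),
            "p_sex": float("nan"),
        }
    )
    return pd.DataFrame(rows)


def build_table2(
    patients: Sequence[PatientRecord], min_overlap_days: int = 1
) -> pd.DataFrame:
    """Diagnosis strata vs antipsychotic use and regimen, plus totals.

    Every patient lands in exactly one stratum; per row and in total,
    monotherapy + polypharmacy equals the user count.
    """
    order = (
        [_CATEGORY_LABELS[c].replace("psychoses", "psychosis") for c in _NAMED_SINGLES]
        + [REST_OF_DIAGNOSES]
        + [label for _, label in _NAMED_PAIRS]
        + [OTHER_COMBINATIONS]
    )
    kind = {
        label: ("single" if i <= order.index(REST_OF_DIAGNOSES) else "comorbidity")
        for i, label in enumerate(order)
    }
    counts = {label: {"n": 0, "users": 0, "mono": 0, "poly": 0} for label in order}
    for patient in patients:
        stratum = table2_stratum(patient)
        summary = classify_regimen(patient, min_overlap_days=min_overlap_days)
        c = counts[stratum]
        c["n"] += 1
        if summary.regimen is not Regimen.NONE:
            c["users"] += 1
            c["mono" if summary.regimen is Regimen.MONOTHERAPY else "poly"] += 1

    n_total = len(patients)
    rows = [
        {
            "stratum": label,
            "kind": kind[label],
            "n": c["n"],
            "pct_of_cohort": percent(c["n"], n_total),
            "antipsychotic_use": c["users"],
            "monotherapy": c["mono"],
            "polytherapy": c["poly"],
        }
        for label, c in counts.items()
        if c["n"] > 0
    ]
    totals = {
        "stratum": "Total",
        "kind": "total",
        "n": n_total,
        "pct_of_cohort": percent(n_total, n_total) if n_total else UNDEFINED_PERCENT,
        "antipsychotic_use": sum(r["antipsychotic_use"] for r in rows),
        "monotherapy": sum(r["monotherapy"] for r in rows),
        "polytherapy": sum(r["polytherapy"] for r in rows),
    }
    return pd.DataFrame(rows + [totals])


def cohort_exposures(
    patients: Sequence[PatientRecord],
) -> dict[tuple[str, str, str], list[PatientDrugExposure]]:
    """Per-presentation lists of patient exposures (antipsychotics only)."""
    grouped: dict[tuple[str, tuple[str, str, str]], list] = defaultdict(list)
    for patient in patients:
        for p in patient.antipsychotic_prescriptions():
            grouped[(patient.patient_id, p.drug.key)].append(p)
    exposures: dict[tuple[str, str, str], list[PatientDrugExposure]] = defaultdict(list)
    for (_, key), rx in grouped.items():
        exposures[key].append(patient_pdd(rx))
    return exposures


def build_table3(
    patients: Sequence[PatientRecord],
    registry: DrugRegistry | None = None,
    count_mode: Literal["exposure", "order"] = "exposure",
) -> list[DrugUtilizationRow]:
    """Per-presentation utilization rows, ordered by drug name.

    ``count_mode='exposure'`` (default) counts one prescription per
    patient per presentation; ``'order'`` counts raw prescription
    rows instead (dose statistics are per-exposure either way).
    """
    registry = registry or default_registry()
    rows = []
    order_counts: dict[tuple[str, str, str], int] = defaultdict(int)
    if count_mode == "order":
        for patient in patients:
            for p in patient.antipsychotic_prescriptions():
                order_counts[p.drug.key] += 1
    for key, exp in cohort_exposures(patients).items():
        row = summarize_drug(exp, registry)
        if count_mode == "order":
            row = DrugUtilizationRow(
                drug=row.drug,
                n_prescriptions=order_counts[key],
                median_pdd_mg=row.median_pdd_mg,
                mean_pdd_mg=row.mean_pdd_mg,
                ci95_mg=row.ci95_mg,
                mean_pdd_over_ddd=row.mean_pdd_over_ddd,
                excessive=row.excessive,
            )
        rows.append(row)
    return sorted(rows, key=lambda r: r.drug.name.lower())


def table3_frame(rows: Sequence[DrugUtilizationRow]) -> pd.DataFrame:
    """Serialize utilization rows with display rounding."""
    return pd.DataFrame(
        {
            "n": r.n_prescriptions,
            "drug": r.drug.name,
            "atc": r.drug.atc.code,
            "ddd_mg": r.drug.ddd_mg_per_day,
            "median_pdd": round_half_up(r.median_pdd_mg, 2),
            "mean_pdd": round_half_up(r.mean_pdd_mg, 2),
            "ci_low": round_half_up(r.ci95_mg[0], 2),
            "ci_high": round_half_up(r.ci95_mg[1], 2),
            "mean_pdd_over_ddd": round_half_up(r.mean_pdd_over_ddd, 2),
            "excessive": r.excessive,
            "route": r.drug.route.value,
            "form": r.drug.form.value,
        }
        for r in rows
    )


@dataclass
class CohortReport:
    """The three tables, per-patient flags and headline rates."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: list[DrugUtilizationRow]
    patient_flags: pd.DataFrame
    headline: dict = field(default_factory=dict)

    @property
    def table3_frame(self) -> pd.DataFrame:
        return table3_frame(self.table3)

    def to_json_dict(self) -> dict:
        return {
            "headline": self.headline,
            "table1": json.loads(self.table1.to_json(orient="records")),
            "table2": json.loads(self.table2.to_json(orient="records")),
            "table3": json.loads(self.table3_frame.to_json(orient="records")),
            "patients": json.loads(self.patient_flags.to_json(orient="records")),
        }


def analyze_cohort(
    patients: Sequence[PatientRecord],
    registry: DrugRegistry | None = None,
    policy: OffLabelPolicy | None = None,
    min_overlap_days: int = 1,
    count_mode: Literal["exposure", "order"] = "exposure",
) -> CohortReport:
    """Run the full pipeline over resolved patient records."""
    registry = registry or default_registry()
    policy = policy or default_policy()

    table1 = build_table1(patients)
    table2 = build_table2(patients, min_overlap_days=min_overlap_days)
    table3 = build_table3(patients, registry, count_mode=count_mode)

    flag_rows = []
    n_users = 0
    for patient in patients:
        summary = classify_regimen(patient, min_overlap_days=min_overlap_days)
        if summary.regimen is not Regimen.NONE:
            n_users += 1
        off = flag_offlabel(patient, policy)
        flag_rows.append(
            {
                "patient_id": patient.patient_id,
                "regimen": summary.regimen.value,
                "max_concurrent_antipsychotics": summary.n_antipsychotics_concurrent_max,
                "n_antipsychotics_total": summary.n_antipsychotics_total,
                "antipsychotic_only": summary.antipsychotic_only,
                "concurrent_pairs": "; ".join(
                    f"{a}+{b}:{d}d" for a, b, d in summary.concurrent_pairs
                ),
                "n_off_label": sum(1 for f in off if not f.on_label),
                "off_label_drugs": "; ".join(f.drug_name for f in off if not f.on_label),
            }
        )
    flags = pd.DataFrame(flag_rows)

    n_patients = len(patients)
    n_rx = sum(r.n_prescriptions for r in table3)
    report = CohortReport(
        table1=table1,
        table2=table2,
        table3=table3,
        patient_flags=flags,
        headline={
            "n_patients": n_patients,
            "n_antipsychotic_users": n_users,
            "percent_users": percent(n_users, n_patients),
            "n_prescriptions": n_rx,
        },
    )
    return report


def write_report(report: CohortReport, outdir: str | Path) -> None:
    """Write each table as CSV, a combined JSON, and text renderings."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.table1.to_csv(outdir / "table1_demographics.csv", index=False)
    report.table2.to_csv(outdir / "table2_regimens.csv", index=False)
    report.table3_frame.to_csv(outdir / "table3_utilization.csv", index=False)
    report.patient_flags.to_csv(outdir / "patient_flags.csv", index=False)
    (outdir / "report.json").write_text(json.dumps(report.to_json_dict(), indent=2))
    text = "\n\n".join(
        [
            "Table 1. Age and sex distribution of psychiatric disorders\n"
            + report.table1.to_string(index=False),
            "Table 2. Antipsychotic medication use according to diagnosis\n"
            + report.table2.to_string(index=False),
            "Table 3. Antipsychotic utilization (ATC/DDD, PDD, PDD/DDD)\n"
            + report.table3_frame.to_string(index=False),
        ]
    )
    (outdir / "report.txt").write_text(text + "\n")
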