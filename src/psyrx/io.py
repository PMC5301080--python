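"""Delimited-text readers and patient-record assembly.

All inputs are UTF-8 delimited text (comma or tab, autodetected) with
a header row; dates are ISO 8601.  Expected columns:

* patients:      patient_id, age, sex, admission_date, discharge_date
* diagnoses:     patient_id, icd10, rank
* prescriptions: patient_id, drug, atc (optional), dose_mg, route,
                 form, times_per_day, interval_days, start_date,
                 end_date — exactly one of times_per_day /
                 interval_days populated per row

Drugs are resolved against the registry by (atc, route, form) when an
ATC code is present, otherwise by normalized name.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Sequence

import pandas as pd

from .atc import DrugRegistry, UnknownDrugError, default_registry
from .dosing import Prescription
from .records import Diagnosis, PatientRecord

__all__ = [
    "load_cohort",
    "read_diagnoses",
    "read_patients",
    "read_prescriptions",
    "resolve_prescription_row",
]


def _read(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", encoding="utf-8")


def _require(df: pd.DataFrame, cols: set[str], what: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{what} table missing columns: {sorted(missing)}")


def _date(value) -> dt.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return pd.Timestamp(value).date()


def read_patients(path) -> pd.DataFrame:
    df = _read(path)
    _require(df, {"patient_id", "age", "sex"}, "patient")
    return df


def read_diagnoses(path) -> pd.DataFrame:
    df = _read(path)
    _require(df, {"patient_id", "icd10"}, "diagnosis")
    if "rank" not in df.columns:
        df["rank"] = 1
    return df


def read_prescriptions(path) -> pd.DataFrame:
    df = _read(path)
    _require(df, {"patient_id", "drug", "dose_mg", "start_date", "end_date"}, "prescription")
    return df


def resolve_prescription_row(row, registry: DrugRegistry) -> Prescription:
    """Build one Prescription from a table row, resolving the drug."""
    atc = getattr(row, "atc", None)
    if atc is not None and not pd.isna(atc) and str(atc).strip():
        drug = registry.lookup(
            str(atc), str(getattr(row, "route", "oral")), str(getattr(row, "form", "standard"))
        )
    else:
        drug = registry.lookup_by_name(str(row.drug))
    def _num(value):
        if value is None or (isinstance(value, str) and not value.strip()) or pd.isna(value):
            return None
        return float(value)

    tpd = _num(getattr(row, "times_per_day", None))
    ivd = _num(getattr(row, "interval_days", None))
    ivd = None if ivd is None else int(ivd)
    return Prescription(
        patient_id=str(row.patient_id),
        drug=drug,
        dose_mg=float(row.dose_mg),
        times_per_day=tpd,
        interval_days=ivd,
        start_date=_date(row.start_date),
        end_date=_date(row.end_date),
    )


def load_cohort(
    patients: pd.DataFrame | str | Path,
    diagnoses: pd.DataFrame | str | Path,
    prescriptions: pd.DataFrame | str | Path,
    registry: DrugRegistry | None = None,
) -> list[PatientRecord]:
    """Join the three tables into per-patient records.

    Prescriptions that cannot be resolved raise
    :class:`~psyrx.atc.UnknownDrugError` naming the offending row.
    """
    registry = registry or default_registry()
    pat = patients if isinstance(patients, pd.DataFrame) else read_patients(patients)
    dx = diagnoses if isinstance(diagnoses, pd.DataFrame) else read_diagnoses(diagnoses)
    rx = (
        prescriptions
        if isinstance(prescriptions, pd.DataFrame)
        else read_prescriptions(prescriptions)
    )

    dx_by_patient: dict[str, list[Diagnosis]] = {}
    for row in dx.itertuples(index=False):
        dx_by_patient.setdefault(str(row.patient_id), []).append(
            Diagnosis(icd10=str(row.icd10), rank=int(getattr(row, "rank", 1)))
        )
    rx_by_patient: dict[str, list[Prescription]] = {}
    for i, row in enumerate(rx.itertuples(index=False)):
        try:
            p = resolve_prescription_row(row, registry)
        except UnknownDrugError as err:
            raise UnknownDrugError(f"prescription row {i}: {err}") from err
        rx_by_patient.setdefault(p.patient_id, []).append(p)

    records = []
    for row in pat.itertuples(index=False):
        pid = str(row.patient_id)
        records.append(
            PatientRecord(
                patient_id=pid,
                age=int(row.age),
                sex=str(row.sex),
                admission_date=_date(getattr(row, "admission_date", None)),
                discharge_date=_date(getattr(row, "discharge_date", None)),
                diagnoses=sorted(dx_by_patient.get(pid, []), key=lambda d: d.rank),
                prescriptions=rx_by_patient.get(pid, []),
            )
        )
    return records


def reference_utilization() -> pd.DataFrame:
    """The bundled published utilization reference table (18 rows)."""
    from importlib import resources

    with resources.files("psyrx.data").joinpath("reference_utilization.csv").open("rb") as fh:
        return pd.read_csv(fh)


def reference_regimens() -> pd.DataFrame:
    """The bundled published diagnosis-by-regimen reference table."""
    from importlib import resources

    with resources.files("psyrx.data").joinpath("reference_regimens.csv").open("rb") as fh:
        return pd.read_csv(fh)
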