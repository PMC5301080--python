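import datetime as dt
import itertools
import random

import pytest

from psyrx.atc import DrugEntry, Form, Route, default_registry, parse_atc
from psyrx.dosing import Prescription
from psyrx.records import Diagnosis, PatientRecord
from psyrx.regimen import (
    Regimen,
    app_share_by_drug,
    classify_regimen,
    max_concurrency,
)

D0 = dt.date(2014, 6, 1)
REG = default_registry()

CLOZAPINE = REG.lookup_by_name("Clozapine")
AMISULPRIDE = REG.lookup_by_name("Amisulpride")
RISPERIDONE = REG.lookup_by_name("Risperidone")
RISPERIDONE_LAI = REG.lookup_by_name("Long-acting risperidone")
OLANZAPINE = REG.lookup_by_name("Olanzapine")
SERTRALINE = DrugEntry(parse_atc("N06AB06"), "Sertraline", Route.ORAL, Form.STANDARD, 50)


def rx(drug, start, end, pid="p1", dose=10.0):
    kwargs = (
        {"interval_days": 28} if drug.form is Form.LONG_ACTING else {"times_per_day": 1.0}
    )
    return Prescription(
        patient_id=pid, drug=drug, dose_mg=dose,
        start_date=D0 + dt.timedelta(days=start), end_date=D0 + dt.timedelta(days=end),
        **kwargs,
    )


def patient(prescriptions, pid="p1"):
    return PatientRecord(
        patient_id=pid, age=40, sex="F",
        diagnoses=[Diagnosis("F20.0")], prescriptions=list(prescriptions),
    )


def oracle_max_concurrency(prescriptions):
    """Brute force: enumerate every day, count distinct active chemicals."""
    ap = [p for p in prescriptions if p.drug.atc.code.startswith("N05A")
          and not p.drug.atc.code.startswith("N05AN")]
    if not ap:
        return 0
    best = 0
    day = min(p.start_date for p in ap)
    last = max(p.end_date for p in ap)
    while day <= last:
        active = {p.drug.atc.code for p in ap if p.start_date <= day <= p.end_date}
        best = max(best, len(active))
        day += dt.timedelta(days=1)
    return best


class TestMaxConcurrency:
    def test_disjoint_ranges_are_sequential_not_concurrent(self):
        assert max_concurrency([rx(CLOZAPINE, 0, 9), rx(AMISULPRIDE, 10, 19)]) == 1

    def test_overlapping_chemicals_are_concurrent(self):
        # clozapine days 1-20 with amisulpride joining on day 5
        assert max_concurrency([rx(CLOZAPINE, 0, 19), rx(AMISULPRIDE, 4, 19)]) == 2

    def test_same_chemical_two_presentations_counts_once(self):
        rxs = [rx(RISPERIDONE, 0, 9), rx(RISPERIDONE_LAI, 0, 27)]
        assert max_concurrency(rxs) == 1
        assert max_concurrency(rxs, count_presentations_separately=True) == 2

    def test_non_antipsychotics_ignored(self):
        assert max_concurrency([rx(SERTRALINE, 0, 9), rx(OLANZAPINE, 0, 9)]) == 1

    def test_min_overlap_days_excludes_short_handover(self):
        rxs = [rx(CLOZAPINE, 0, 10), rx(OLANZAPINE, 10, 20)]  # one shared day
        assert max_concurrency(rxs, min_overlap_days=1) == 2
        assert max_concurrency(rxs, min_overlap_days=2) == 1

    def test_matches_brute_force_oracle_on_randomized_instances(self):
        drugs = [CLOZAPINE, AMISULPRIDE, RISPERIDONE, RISPERIDONE_LAI, OLANZAPINE, SERTRALINE]
        rng = random.Random(20140601)
        for _ in range(500):
            rxs = []
            for _ in range(rng.randint(0, 6)):
                start = rng.randint(0, 25)
                rxs.append(rx(rng.choice(drugs), start, start + rng.randint(0, 15)))
            assert max_concurrency(rxs) == oracle_max_concurrency(rxs)

    def test_permutation_invariance(self):
        rxs = [rx(CLOZAPINE, 0, 12), rx(AMISULPRIDE, 5, 20), rx(OLANZAPINE, 18, 25)]
        results = {max_concurrency(list(p)) for p in itertools.permutations(rxs)}
        assert len(results) == 1


class TestClassifyRegimen:
    def test_no_prescriptions_is_none(self):
        s = classify_regimen(patient([]))
        assert s.regimen is Regimen.NONE
        assert s.n_antipsychotics_total == 0

    def test_one_antipsychotic_plus_antidepressant_is_monotherapy(self):
        s = classify_regimen(patient([rx(OLANZAPINE, 0, 9), rx(SERTRALINE, 0, 9)]))
        assert s.regimen is Regimen.MONOTHERAPY
        assert not s.antipsychotic_only

    def test_antipsychotic_only_flag(self):
        assert classify_regimen(patient([rx(OLANZAPINE, 0, 9)])).antipsychotic_only

    def test_concurrent_antipsychotics_are_polypharmacy(self):
        s = classify_regimen(patient([rx(CLOZAPINE, 0, 19), rx(AMISULPRIDE, 4, 19)]))
        assert s.regimen is Regimen.POLYPHARMACY
        assert s.concurrent_pairs == (("N05AH02", "N05AL05", 16),)

    def test_sequential_switch_is_monotherapy(self):
        s = classify_regimen(patient([rx(CLOZAPINE, 0, 9), rx(OLANZAPINE, 10, 19)]))
        assert s.regimen is Regimen.MONOTHERAPY
        assert s.n_antipsychotics_total == 2


class TestAppShareByDrug:
    def _cohort(self, n_users, n_poly, drug=CLOZAPINE):
        cohort = []
        for i in range(n_users):
            rxs = [rx(drug, 0, 19, pid=f"p{i}")]
            if i < n_poly:
                rxs.append(rx(OLANZAPINE if drug is not OLANZAPINE else RISPERIDONE,
                              0, 19, pid=f"p{i}"))
            cohort.append(patient(rxs, pid=f"p{i}"))
        return cohort

    @pytest.mark.parametrize(
        "n_users,n_poly,expected_pct",
        [(11, 9, 81.8), (17, 12, 70.6), (5, 0, 0.0)],
    )
    def test_polypharmacy_share(self, n_users, n_poly, expected_pct):
        shares = app_share_by_drug(self._cohort(n_users, n_poly))
        users, poly, pct = shares["Clozapine"]
        assert (users, poly) == (n_users, n_poly)
        assert pct == expected_pct

    def test_zero_user_drugs_omitted(self):
        shares = app_share_by_drug(self._cohort(3, 0))
        assert "Ziprasidone" not in shares
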