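import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psyrx.atc import DrugEntry, Form, Route, parse_atc
from psyrx.dosing import Prescription, daily_dose, patient_pdd

OLANZAPINE = DrugEntry(parse_atc("N05AH03"), "Olanzapine", Route.ORAL, Form.STANDARD, 10)
FLUPHENAZINE = DrugEntry(
    parse_atc("N05AB02"), "Fluphenazine", Route.INJECTABLE, Form.LONG_ACTING, 1
)
PALIPERIDONE_LAI = DrugEntry(
    parse_atc("N05AX13"), "Long-acting paliperidone", Route.INJECTABLE, Form.LONG_ACTING, 2.5
)

D0 = dt.date(2014, 6, 1)


def oral(dose, start, end, tpd=1.0, pid="p1", drug=OLANZAPINE):
    return Prescription(
        patient_id=pid, drug=drug, dose_mg=dose,
        start_date=D0 + dt.timedelta(days=start), end_date=D0 + dt.timedelta(days=end),
        times_per_day=tpd,
    )


def depot(dose, interval, start, end, drug=FLUPHENAZINE, pid="p1"):
    return Prescription(
        patient_id=pid, drug=drug, dose_mg=dose,
        start_date=D0 + dt.timedelta(days=start), end_date=D0 + dt.timedelta(days=end),
        interval_days=interval,
    )


def brute_force_pdd(prescriptions):
    """Independent per-day ledger: spread each order uniformly, sum, average."""
    ledger = {}
    for p in prescriptions:
        dd = p.dose_mg / p.interval_days if p.interval_days else p.dose_mg * p.times_per_day
        day = p.start_date
        while day <= p.end_date:
            ledger[day] = ledger.get(day, 0.0) + dd
            day += dt.timedelta(days=1)
    exposed = [v for v in ledger.values() if v > 0]
    return sum(exposed) / len(exposed)


class TestDailyDose:
    def test_daily_schedule_multiplies_frequency(self):
        assert daily_dose(oral(5, 0, 9, tpd=2)) == 10

    @pytest.mark.parametrize(
        "dose,interval,drug,expected_2dp",
        [
            (25, 28, FLUPHENAZINE, 0.89),       # depot fluphenazine
            (100, 28, PALIPERIDONE_LAI, 3.57),  # LAI paliperidone
        ],
    )
    def test_depot_spreads_over_interval(self, dose, interval, drug, expected_2dp):
        assert daily_dose(depot(dose, interval, 0, 27, drug)) == pytest.approx(
            expected_2dp, abs=5e-3
        )

    def test_interval_one_day_is_identity(self):
        assert daily_dose(depot(7.5, 1, 0, 5)) == 7.5

    def test_depot_equals_mean_of_injection_ledger(self):
        # full dose at injection, zero otherwise, averaged over the interval
        dose, interval = 150, 28
        ledger = [dose] + [0.0] * (interval - 1)
        assert daily_dose(depot(dose, interval, 0, 27, PALIPERIDONE_LAI)) == pytest.approx(
            sum(ledger) / interval
        )

    def test_depot_schedule_requires_long_acting_form(self):
        with pytest.raises(ValueError, match="not long-acting"):
            Prescription(
                patient_id="p1", drug=OLANZAPINE, dose_mg=10,
                start_date=D0, end_date=D0, interval_days=28,
            )

    @pytest.mark.parametrize("kwargs", [{"dose": -5}, {"dose": 0}])
    def test_nonpositive_dose_rejected(self, kwargs):
        with pytest.raises(ValueError):
            oral(kwargs["dose"], 0, 5)


class TestPatientPdd:
    def test_constant_dose_is_identity(self):
        exp = patient_pdd([oral(10, 0, 13)])
        assert exp.pdd_mg_per_day == 10
        assert exp.exposed_days == 14  # inclusive both ends

    def test_one_day_order_has_one_exposed_day(self):
        assert patient_pdd([oral(10, 3, 3)]).exposed_days == 1

    def test_titration_averages_day_by_day(self):
        # 5 mg bid for 4 days then 10 mg bid for 4 days -> (4*10 + 4*20)/8
        rx = [oral(5, 0, 3, tpd=2), oral(10, 4, 7, tpd=2)]
        exp = patient_pdd(rx)
        assert exp.pdd_mg_per_day == pytest.approx(15)
        assert exp.pdd_mg_per_day == pytest.approx(brute_force_pdd(rx))

    def test_concurrent_same_drug_orders_sum(self):
        rx = [oral(5, 0, 9), oral(5, 0, 9)]
        exp = patient_pdd(rx)
        assert exp.pdd_mg_per_day == pytest.approx(10)
        assert exp.pdd_mg_per_day == pytest.approx(brute_force_pdd(rx))

    def test_empty_list_flags_no_exposure(self):
        exp = patient_pdd([])
        assert exp.no_exposure and exp.pdd_mg_per_day == 0

    def test_window_restricts_exposure(self):
        exp = patient_pdd([oral(10, 0, 19)], window=(D0, D0 + dt.timedelta(days=4)))
        assert exp.exposed_days == 5

    def test_mixed_patients_rejected(self):
        with pytest.raises(ValueError):
            patient_pdd([oral(10, 0, 5, pid="a"), oral(10, 0, 5, pid="b")])

    @settings(derandomize=True, max_examples=50)
    @given(
        doses=st.lists(st.floats(0.5, 500), min_size=1, max_size=4),
        k=st.floats(0.1, 10),
    )
    def test_scaling_doses_scales_pdd(self, doses, k):
        rx = [oral(d, 3 * i, 3 * i + 2) for i, d in enumerate(doses)]
        scaled = [oral(d * k, 3 * i, 3 * i + 2) for i, d in enumerate(doses)]
        assert patient_pdd(scaled).pdd_mg_per_day == pytest.approx(
            k * patient_pdd(rx).pdd_mg_per_day
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        dose=st.floats(1, 400),
        total=st.integers(2, 30),
        cut=st.integers(1, 29),
    )
    def test_splitting_constant_order_preserves_pdd(self, dose, total, cut):
        cut = min(cut, total - 1)
        whole = [oral(dose, 0, total - 1)]
        split = [oral(dose, 0, cut - 1), oral(dose, cut, total - 1)]
        assert patient_pdd(split).pdd_mg_per_day == pytest.approx(
            patient_pdd(whole).pdd_mg_per_day
        )
        assert patient_pdd(split).exposed_days == total
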