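"""Record validation, CSV round-trips, reliability filtering and
retention/compliance metrics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_record
from vfhome import (
    Device,
    Eye,
    FormatError,
    InsufficientDataError,
    ReliabilityCriteria,
    Setting,
    VFTestRecord,
    ValidationError,
    apply_reliability_filter,
    average_test_frequency,
    compliance_by_period,
    read_tests,
    retention_rate,
    write_tests,
)
from vfhome.records import DAYS_PER_MONTH


def record_strategy():
    pct = st.floats(0, 100, allow_nan=False)
    opt = st.one_of(st.none(), st.floats(0, 100, allow_nan=False))
    return st.builds(
        VFTestRecord,
        patient_id=st.from_regex(r"P[0-9]{3}", fullmatch=True),
        eye=st.sampled_from(list(Eye)),
        device=st.sampled_from(list(Device)),
        setting=st.sampled_from(list(Setting)),
        t_days=st.integers(0, 4000),
        md_db=st.one_of(st.none(), st.floats(-35, 10, allow_nan=False)),
        psd_db=st.one_of(st.none(), st.floats(0, 20, allow_nan=False)),
        vfi_pct=opt,
        fp_pct=pct,
        fn_pct=pct,
        fl_pct=pct,
    )


class TestValidation:
    @pytest.mark.parametrize("field,value", [
        ("fp_pct", 120.0), ("fn_pct", -1.0), ("fl_pct", 101.0),
        ("md_db", -40.0), ("md_db", 11.0), ("psd_db", -0.5),
        ("vfi_pct", 120.0), ("t_days", -3),
    ])
    def test_out_of_range_fields_rejected(self, field, value):
        with pytest.raises(ValidationError):
            make_record(**{field: value})

    def test_criteria_must_be_positive(self):
        with pytest.raises(ValidationError):
            ReliabilityCriteria(fp_max_pct=0.0)


class TestCsvIO:
    def test_well_formed_file_round_trips(self, tmp_path):
        records = [make_record(t_days=i * 15, md_db=-5.0 + i)
                   for i in range(3)]
        path = tmp_path / "t.csv"
        write_tests(path, records, header_comment="fixture")
        assert read_tests(path) == records

    @given(st.lists(record_strategy(), min_size=1, max_size=30))
    def test_round_trip_identity_randomized(self, records):
        import io

        from vfhome.records import CSV_COLUMNS

        # round-trip through an on-disk file per example is slow; use tmp
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".csv",
                                         delete=False) as fh:
            path = fh.name
        write_tests(path, records)
        assert read_tests(path) == records

    def test_out_of_range_row_reports_row_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_tests(path, [make_record(), make_record(t_days=15)])
        text = path.read_text().replace("4.7", "120.0", 1)
        path.write_text(text)
        with pytest.raises(ValidationError) as err:
            read_tests(path)
        assert err.value.row == 1

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,eye\nP001,OD\n")
        with pytest.raises(FormatError, match="missing required column"):
            read_tests(path)


class TestReliabilityFilter:
    def test_study_mean_indices_pass(self):
        rec = make_record(fp_pct=4.7, fn_pct=5.0, fl_pct=9.6)
        assert ReliabilityCriteria().is_reliable(rec)

    @pytest.mark.parametrize("field,value", [
        ("fp_pct", 20.0), ("fn_pct", 20.0), ("fl_pct", 33.0)])
    def test_boundary_values_fail_strict_criteria(self, field, value):
        rec = make_record(**{field: value})
        assert not ReliabilityCriteria().is_reliable(rec)

    def test_reliability_rate_matches_constructed_counts(self):
        # 1191 reliable + 243 failing (fixation loss at the bound)
        tests = [make_record(t_days=i) for i in range(1191)]
        tests += [make_record(t_days=i, fl_pct=33.0) for i in range(243)]
        reliable, rate = apply_reliability_filter(tests)
        assert len(reliable) == 1191
        assert rate == pytest.approx(1191 / 1434)

    def test_rate_monotone_in_thresholds(self, rng):
        tests = [make_record(fp_pct=rng.uniform(0, 40),
                             fn_pct=rng.uniform(0, 40),
                             fl_pct=rng.uniform(0, 60), t_days=i)
                 for i in range(200)]
        rates = [apply_reliability_filter(
            tests, ReliabilityCriteria(fp_max_pct=fp, fn_max_pct=20,
                                       fl_max_pct=33))[1]
            for fp in (30, 20, 10, 5)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_empty_collection_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            apply_reliability_filter([])


class TestRetention:
    def test_18_of_25_gives_072(self):
        enrolled = [f"P{i:03d}" for i in range(25)]
        tests = [make_record(patient_id=pid) for pid in enrolled[:18]]
        assert retention_rate(tests, enrolled) == pytest.approx(0.72)

    def test_no_home_tests_gives_zero(self):
        tests = [make_record(setting=Setting.CLINIC,
                             device=Device.CLINIC_SAP)]
        assert retention_rate(tests, ["P001", "P002"]) == 0.0

    def test_all_tested_gives_one(self):
        tests = [make_record(patient_id="A"), make_record(patient_id="B")]
        assert retention_rate(tests, ["A", "B"]) == 1.0

    def test_empty_enrolled_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            retention_rate([], [])


def _sessions(pid, days):
    """One bilateral session (two records) per day."""
    out = []
    for d in days:
        out.append(make_record(patient_id=pid, eye=Eye.OD, t_days=d))
        out.append(make_record(patient_id=pid, eye=Eye.OS, t_days=d))
    return out


class TestCompliance:
    def test_12_of_18_meeting_twice_monthly_gives_two_thirds(self):
        tests = []
        ids = [f"P{i:03d}" for i in range(18)]
        for i, pid in enumerate(ids):
            n = 12 if i < 12 else 5  # 12 sessions needed in 6 months
            tests += _sessions(pid, [int(k * 14) for k in range(n)])
        comp = compliance_by_period(tests, ids, period_months=6,
                                    freq_per_month=2, total_months=6)
        assert comp[0] == pytest.approx(12 / 18, abs=1e-12)

    def test_daily_testing_fully_compliant(self):
        ids = ["A", "B"]
        tests = [make_record(patient_id=pid, t_days=d)
                 for pid in ids for d in range(730)]
        comp = compliance_by_period(tests, ids)
        assert comp == [1.0, 1.0, 1.0, 1.0]

    def test_bilateral_session_counts_once(self):
        # two eyes on the same day must count as one test event
        tests = _sessions("A", [0, 15, 30])
        comp = compliance_by_period(tests, ["A"], period_months=2,
                                    freq_per_month=1, total_months=2)
        assert comp == [1.0]
        comp2 = compliance_by_period(tests, ["A"], period_months=2,
                                     freq_per_month=2, total_months=2)
        assert comp2 == [0.0]  # 3 sessions < 4 required

    def test_matches_brute_force_recount(self, rng):
        ids = [f"P{i:02d}" for i in range(10)]
        tests = []
        days_by_pid = {}
        for pid in ids:
            days = sorted(rng.choice(730, size=rng.integers(1, 60),
                                     replace=False).tolist())
            days_by_pid[pid] = days
            tests += _sessions(pid, days)
        for period, freq, total in [(6, 2, 24), (2, 1, 24), (3, 1.5, 24)]:
            got = compliance_by_period(tests, ids, period, freq, total)
            for w, frac in enumerate(got):
                lo = w * period * DAYS_PER_MONTH
                hi = (w + 1) * period * DAYS_PER_MONTH
                n_ok = sum(
                    1 for pid in ids
                    if sum(lo <= d < hi for d in days_by_pid[pid])
                    >= freq * period)
                assert frac == pytest.approx(n_ok / len(ids))

    def test_freq2_never_exceeds_freq1(self, rng):
        ids = [f"P{i:02d}" for i in range(12)]
        tests = []
        for pid in ids:
            days = sorted(rng.choice(730, size=rng.integers(5, 50),
                                     replace=False).tolist())
            tests += _sessions(pid, days)
        c1 = compliance_by_period(tests, ids, freq_per_month=1)
        c2 = compliance_by_period(tests, ids, freq_per_month=2)
        assert all(b <= a for a, b in zip(c1, c2))

    def test_zero_participants_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            compliance_by_period([], [])


class TestAverageFrequency:
    @pytest.mark.parametrize("n,window,expect", [
        (38, 24, 38 / 24), (0, 24, 0.0), (52, 24, 52 / 24)])
    def test_sessions_per_month(self, n, window, expect):
        tests = _sessions("A", [int(d * 13.9) for d in range(n)])
        got = average_test_frequency(tests, "A", window)
        assert got == pytest.approx(expect)
        if n == 38:
            assert round(got, 1) == 1.6

    def test_window_must_be_positive(self):
        with pytest.raises(ValidationError):
            average_test_frequency([], "A", 0)
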