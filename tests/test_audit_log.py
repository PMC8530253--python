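import datetime as dt

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from collabnet.audit_log import (
    DEFAULT_PERIODS,
    ActionEvent,
    AuditLogError,
    StudyPeriod,
    filter_patients,
    partition_by_period,
    read_events,
    read_patients,
    to_patient_days,
    write_events,
)


class TestReadEvents:
    def test_well_formed_file_parses_every_row(self, events_csv):
        events, report = read_events(events_csv)
        assert len(events) == 4
        assert report.n_read == 4
        assert report.n_rejected == 0
        # sorted by (day, clinician, patient)
        assert list(events["clinician_id"]) == ["d1", "n1", "n1", "n2"]

    def test_unknown_category_row_is_rejected_with_reason(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text(
            "clinician_id,specialty,patient_id,timestamp,action_category\n"
            "n1,nicu_nurse,p1,2019-09-03T08:00:00,note\n"
            "n1,nicu_nurse,p1,2019-09-03T09:00:00,zoom_call\n"
            "n2,nicu_nurse,p1,2019-09-03T10:00:00,order\n"
            "d1,neonatologist,p1,2019-09-03T11:00:00,order\n"
        )
        events, report = read_events(path)
        assert len(events) == 3
        assert report.n_rejected == 1
        line, reason = report.rejects[0]
        assert line == 3
        assert "zoom_call" in reason and "category" in reason

    def test_header_only_file_yields_empty_frame(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("clinician_id,specialty,patient_id,timestamp,action_category\n")
        events, report = read_events(path)
        assert events.empty and report.n_read == 0 and report.n_rejected == 0

    def test_missing_column_is_hard_error_naming_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("clinician_id,specialty,timestamp,action_category\nx,y,z,w\n")
        with pytest.raises(AuditLogError, match="patient_id"):
            read_events(path)

    def test_unparseable_timestamp_rejected_and_counted(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text(
            "clinician_id,specialty,patient_id,timestamp,action_category\n"
            "n1,nicu_nurse,p1,not-a-date,note\n"
            "n1,nicu_nurse,p1,2019-09-03,note\n"
        )
        events, report = read_events(path)
        assert len(events) == 1  # date-only timestamps are fine
        assert report.rejects[0][0] == 2

    def test_clinician_with_two_specialties_is_hard_error(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text(
            "clinician_id,specialty,patient_id,timestamp,action_category\n"
            "n1,nicu_nurse,p1,2019-09-03T08:00:00,note\n"
            "n1,resident,p2,2019-09-04T08:00:00,note\n"
        )
        with pytest.raises(AuditLogError, match="n1"):
            read_events(path)

    def test_round_trip_reproduces_canonical_bytes(self, events_csv, tmp_path):
        events, _ = read_events(events_csv)
        first = tmp_path / "w1.csv"
        write_events(events, first)
        events2, _ = read_events(first)
        second = tmp_path / "w2.csv"
        write_events(events2, second)
        assert first.read_bytes() == second.read_bytes()


class TestActionEvent:
    def test_rejects_empty_ids_and_bad_category(self):
        ts = dt.datetime(2019, 9, 3, 8)
        with pytest.raises(AuditLogError):
            ActionEvent("", "s", "p1", ts, "note")
        with pytest.raises(AuditLogError):
            ActionEvent("c1", "s", "p1", ts, "telepathy")
        ev = ActionEvent("c1", "s", "p1", ts, "note")
        assert ev.day == dt.date(2019, 9, 3)


class TestPeriods:
    @pytest.mark.parametrize(
        "day,expected",
        [
            (dt.date(2019, 12, 31), "pre"),   # inclusive end of first window
            (dt.date(2020, 3, 1), "intra"),   # inclusive start of second
            (dt.date(2020, 1, 15), None),     # the gap is dropped
        ],
    )
    def test_boundary_assignment(self, day, expected):
        events = pd.DataFrame(
            {"clinician_id": ["c1"], "specialty": ["s"], "patient_id": ["p1"],
             "timestamp": [pd.Timestamp(day)], "day": [day],
             "action_category": ["note"]}
        )
        parts, dropped = partition_by_period(events, DEFAULT_PERIODS)
        if expected is None:
            assert len(dropped) == 1
            assert all(df.empty for df in parts.values())
        else:
            assert len(parts[expected]) == 1 and dropped.empty

    def test_overlapping_periods_are_rejected(self):
        periods = [
            StudyPeriod("a", dt.date(2020, 1, 1), dt.date(2020, 3, 1)),
            StudyPeriod("b", dt.date(2020, 3, 1), dt.date(2020, 5, 1)),
        ]
        with pytest.raises(AuditLogError, match="overlap"):
            partition_by_period(pd.DataFrame(columns=["day"]), periods)

    def test_partition_conserves_events(self):
        days = [dt.date(2019, 10, 1), dt.date(2020, 2, 1), dt.date(2020, 4, 1)] * 3
        events = pd.DataFrame(
            {"clinician_id": "c", "specialty": "s", "patient_id": "p",
             "timestamp": pd.to_datetime(days), "day": days,
             "action_category": "note"}
        )
        parts, dropped = partition_by_period(events, DEFAULT_PERIODS)
        assert sum(map(len, parts.values())) + len(dropped) == len(events)

    def test_inverted_window_is_invalid(self):
        with pytest.raises(AuditLogError):
            StudyPeriod("x", dt.date(2020, 2, 1), dt.date(2020, 1, 1))


class TestPatientDays:
    def _events(self, rows):
        return pd.DataFrame(
            {"clinician_id": [r[0] for r in rows],
             "specialty": "s",
             "patient_id": [r[1] for r in rows],
             "timestamp": [pd.Timestamp(r[2]) for r in rows],
             "day": [r[2] for r in rows],
             "action_category": "note"}
        )

    def test_repeated_actions_collapse_to_one_unit(self):
        d = dt.date(2019, 9, 3)
        events = self._events([("c1", "p1", d)] * 5)
        units = to_patient_days(events)
        assert len(units) == 1
        assert tuple(units.iloc[0]) == ("c1", "p1", d)

    def test_distinct_triples_are_all_kept(self):
        d1, d2 = dt.date(2019, 9, 3), dt.date(2019, 9, 4)
        events = self._events([("c1", "p1", d1), ("c1", "p1", d2), ("c2", "p1", d1)])
        assert len(to_patient_days(events)) == 3

    def test_empty_events_give_empty_units(self):
        assert to_patient_days(self._events([])).empty

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.permutations(list(range(8))))
    def test_reduction_is_order_invariant_and_idempotent(self, order):
        d = dt.date(2019, 9, 3)
        rows = [("c1", "p1", d), ("c1", "p1", d), ("c2", "p1", d),
                ("c2", "p2", d), ("c1", "p2", d + dt.timedelta(days=1)),
                ("c3", "p1", d), ("c3", "p1", d), ("c2", "p1", d)]
        events = self._events([rows[i] for i in order])
        units = to_patient_days(events)
        again = to_patient_days(
            units.assign(timestamp=pd.to_datetime(units["day"]),
                         specialty="s", action_category="note")
        )
        baseline = to_patient_days(self._events(rows))
        pd.testing.assert_frame_equal(units, baseline)
        pd.testing.assert_frame_equal(units, again)


class TestFilterPatients:
    def _patients(self, flags):
        return pd.DataFrame(
            {"patient_id": list(flags), "excluded": list(flags.values())}
        )

    def _events(self, pids):
        return pd.DataFrame(
            {"clinician_id": "c", "specialty": "s", "patient_id": pids,
             "timestamp": pd.Timestamp("2019-09-03"),
             "day": dt.date(2019, 9, 3), "action_category": "note"}
        )

    def test_flagged_patients_events_removed(self):
        events, n = filter_patients(
            self._events(["p1", "p2", "p1"]), self._patients({"p1": True, "p2": False})
        )
        assert set(events["patient_id"]) == {"p2"} and n == 1

    def test_no_flags_is_identity(self):
        ev = self._events(["p1", "p2"])
        out, n = filter_patients(ev, self._patients({"p1": False, "p2": False}))
        assert len(out) == 2 and n == 0

    def test_all_flagged_warns_and_empties(self):
        with pytest.warns(UserWarning, match="all patients"):
            out, n = filter_patients(
                self._events(["p1", "p2"]), self._patients({"p1": True, "p2": True})
            )
        assert out.empty and n == 2

    def test_unknown_patient_policy(self):
        ev = self._events(["p1", "ghost"])
        with pytest.warns(UserWarning, match="absent"):
            kept, _ = filter_patients(ev, self._patients({"p1": False}))
        assert len(kept) == 2  # warn-and-keep default
        with pytest.warns(UserWarning):
            dropped, _ = filter_patients(ev, self._patients({"p1": False}),
                                         on_unknown="drop")
        assert list(dropped["patient_id"]) == ["p1"]
        with pytest.raises(AuditLogError):
            filter_patients(ev, self._patients({"p1": False}), on_unknown="error")


class TestReadPatients:
    def test_parses_and_computes_los(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(
            "patient_id,admit_date,discharge_date,sex,race,ethnicity,age_days,"
            "disposition,excluded\n"
            "p1,2019-09-01,2019-09-11,female,white,non_hispanic,0,home,0\n"
            "p2,2019-09-05,2019-09-01,male,white,non_hispanic,0,home,0\n"
        )
        patients, report = read_patients(path)
        assert len(patients) == 1
        assert patients.loc[0, "los_days"] == 10
        assert report.n_rejected == 1
        assert "discharge precedes" in report.rejects[0][1]
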