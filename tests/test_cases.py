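"""Case windows, date-filter policy, retrieval outcomes, cohort summary."""

from __future__ import annotations

import datetime as dt

import pytest

from fhirdq.cases import (
    STUDY_END, STUDY_START, CaseWindow, Demographics, PatientCase,
    RetrievalOutcome, WindowMode, apply_window_policy, classify_retrieval,
    compute_case_window, summarize_cohort,
)
from fhirdq.records import record_from_resource

from conftest import make_condition, make_observation

D = dt.date


class TestComputeCaseWindow:
    def test_limited_window_with_encounter_end(self):
        w = compute_case_window(D(2021, 1, 1), D(2021, 1, 18), D(2021, 1, 20))
        assert (w.mode, w.start, w.end) == (
            WindowMode.LIMITED, D(2021, 1, 1), D(2021, 1, 30))

    def test_limited_window_falls_back_to_encounter_start(self):
        w = compute_case_window(D(2021, 1, 1), D(2021, 1, 18), None)
        assert (w.mode, w.start, w.end) == (
            WindowMode.LIMITED, D(2021, 1, 1), D(2021, 1, 28))

    def test_entire_study_without_immunization_date(self):
        w = compute_case_window(None, None, None)
        assert (w.mode, w.start, w.end) == (
            WindowMode.ENTIRE_STUDY, D(2020, 12, 14), D(2023, 5, 1))

    def test_encounter_before_immunization_rejected(self):
        with pytest.raises(ValueError, match="mis-paired"):
            compute_case_window(D(2021, 5, 1), D(2021, 1, 1), D(2021, 1, 2))


def _case(window, resources):
    return PatientCase(partner_id="pA", patient_id="p1", window=window,
                       resources=resources)


def _rec(resource):
    return record_from_resource(resource, "pA", "p1")


class TestWindowPolicy:
    window = CaseWindow(WindowMode.LIMITED, D(2021, 3, 1), D(2021, 3, 20))

    def test_observation_inside_retained(self):
        case = _case(self.window, [_rec(make_observation())])  # 2021-03-02
        assert len(apply_window_policy(case).resources) == 1

    def test_docref_outside_removed(self):
        doc = {"resourceType": "DocumentReference", "id": "d1",
               "status": "current", "date": "2021-03-31",
               "type": {"text": "Progress note"}}
        case = _case(self.window, [_rec(doc)])
        assert apply_window_policy(case).resources == []

    def test_full_history_type_retained_outside_window(self):
        cond = make_condition()
        cond["onsetDateTime"] = "2015-01-01"
        case = _case(self.window, [_rec(cond)])
        assert len(apply_window_policy(case).resources) == 1

    def test_undated_filtered_type_retained_and_flagged(self):
        obs = make_observation()
        del obs["effectiveDateTime"]
        case = _case(self.window, [_rec(obs)])
        out = apply_window_policy(case)
        assert len(out.resources) == 1 and len(out.flagged_undated) == 1

    def test_period_overlap_counts_as_inside(self):
        obs = make_observation()
        del obs["effectiveDateTime"]
        obs["effectivePeriod"] = {"start": "2021-02-20", "end": "2021-03-05"}
        case = _case(self.window, [_rec(obs)])
        assert len(apply_window_policy(case).resources) == 1

    def test_entire_study_drops_only_out_of_study_records(self):
        window = CaseWindow(WindowMode.ENTIRE_STUDY, STUDY_START, STUDY_END)
        inside = make_observation(rid="in")
        before = make_observation(rid="out")
        before["effectiveDateTime"] = "2019-06-01"
        case = _case(window, [_rec(inside), _rec(before)])
        out = apply_window_policy(case)
        assert [r.resource_id for r in out.resources] == ["in"]


class TestClassifyRetrieval:
    @pytest.mark.parametrize("matched,flag,expected", [
        (2, False, RetrievalOutcome.MULTIPLE_MATCH),
        (0, False, RetrievalOutcome.NO_MATCH),
        (1, True, RetrievalOutcome.BREAK_THE_GLASS_DENIED),
        (1, False, RetrievalOutcome.SUCCESS),
        (5, True, RetrievalOutcome.MULTIPLE_MATCH),
    ])
    def test_outcomes(self, matched, flag, expected):
        assert classify_retrieval(matched, flag) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            classify_retrieval(-1)


def _cohort(n, **groups):
    """n cases whose demographics cycle through the given group counts."""
    def expand(mapping):
        out = []
        for name, count in mapping.items():
            out.extend([name] * count)
        return out

    window = CaseWindow(WindowMode.LIMITED, D(2021, 1, 1), D(2021, 2, 1))
    lists = {attr: expand(mapping) for attr, mapping in groups.items()}
    cases = []
    for i in range(n):
        demo = Demographics(**{attr: vals[i] for attr, vals in lists.items()})
        cases.append(PatientCase(f"p{i % 7}", f"pt{i}", window, demo))
    return cases


class TestCohortSummary:
    def test_pilot_cohort_percentages(self):
        """283 cases: 249 COVID-19 -> 88.0%, 223 Non-Hispanic -> 78.8%."""
        cases = _cohort(
            283,
            immunization_type={"COVID-19": 249, "Other": 34},
            ethnicity={"Hispanic": 29, "Non-Hispanic": 223, "Unknown": 31},
        )
        summary = summarize_cohort(cases)
        pct = {(r.category, r.group): r.percent for r in summary.rows}
        assert pct[("Immunization type", "COVID-19")] == 88.0
        assert pct[("Ethnicity", "Non-Hispanic")] == 78.8

    def test_zero_count_group_absent_or_zero(self):
        cases = _cohort(10, gender={"Female": 10})
        summary = summarize_cohort(cases)
        rows = [r for r in summary.rows if r.category == "Gender"]
        assert rows[0].percent == 100.0

    def test_percent_sums_near_100(self, small_cases):
        ok = [c for c in small_cases
              if c.retrieval_outcome == RetrievalOutcome.SUCCESS]
        summary = summarize_cohort(ok)
        by_cat = {}
        for r in summary.rows:
            if r.category != "Total":
                by_cat.setdefault(r.category, 0.0)
                by_cat[r.category] += r.percent
        for cat, total in by_cat.items():
            assert abs(total - 100.0) <= 0.3, cat

    def test_missing_demographics_counted_unknown(self):
        cases = _cohort(4, gender={"Male": 4})
        for c in cases:
            c.demographics.race = None
        summary = summarize_cohort(cases)
        race_rows = {r.group: r.count for r in summary.rows
                     if r.category == "Race"}
        assert race_rows == {"Unknown": 4}

    def test_failed_cases_rejected(self):
        cases = _cohort(2, gender={"Male": 2})
        cases[0].retrieval_outcome = RetrievalOutcome.NO_MATCH
        with pytest.raises(ValueError):
            summarize_cohort(cases)
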