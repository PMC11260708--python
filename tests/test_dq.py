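"""Data-quality engine: evaluators, registry, suite execution."""

from __future__ import annotations

import datetime as dt
from collections import defaultdict

import pytest

from fhirdq.cases import CaseWindow, PatientCase, WindowMode
from fhirdq.dq import (
    CaseContext, Category, DQTest, Outcome, Priority, RegistrationError,
    STUDY_REGISTRY_MANIFEST, eval_code_conformance,
    eval_completeness, eval_temporal_plausibility, manifest_totals,
    register_builtin_tests, run_suite, run_test,
)
from fhirdq.dq import TestRegistry as Registry
from fhirdq.records import record_from_resource

from conftest import (
    make_condition, make_immunization, make_observation, make_patient,
)

WINDOW = CaseWindow(WindowMode.LIMITED, dt.date(2021, 1, 1), dt.date(2021, 2, 1))


def _rec(resource, partner="pA"):
    return record_from_resource(resource, partner, "p1")


def _ctx(patient=None, query=dt.date(2023, 6, 1), n_patients=1, case=None):
    return CaseContext(patient=patient, query_date=query,
                       n_patients=n_patients, case=case)


class TestEvalCompleteness:
    def test_present_value_passes(self):
        rec = _rec(make_immunization(lotNumber="EW0182"))
        assert eval_completeness(rec, "lotNumber") is Outcome.PASS

    def test_missing_element_fails(self):
        assert eval_completeness(
            _rec(make_immunization()), "manufacturer") is Outcome.FAIL

    @pytest.mark.parametrize("value", ["", "   ", []])
    def test_empty_values_fail(self, value):
        rec = _rec(make_immunization(lotNumber=value))
        assert eval_completeness(rec, "lotNumber") is Outcome.FAIL

    def test_recorded_false_counts_as_present(self):
        rec = _rec(make_patient(deceasedBoolean=False))
        assert eval_completeness(rec, "deceasedBoolean") is Outcome.PASS

    def test_scope_predicate_gives_not_applicable(self):
        living = _rec(make_patient())
        out = eval_completeness(
            living, "deceasedDateTime",
            applicable_if=lambda r: r.element("deceasedBoolean") is True)
        assert out is Outcome.NOT_APPLICABLE


SNOMED = "http://snomed.info/sct"


class TestEvalCodeConformance:
    def test_allowed_system_passes(self):
        rec = _rec(make_condition())
        assert eval_code_conformance(rec, "code", {SNOMED}) is Outcome.PASS

    def test_zero_code_fails(self):
        obs = make_observation()
        obs["code"] = {"coding": [{"system": "http://loinc.org", "code": "0"}]}
        assert eval_code_conformance(
            _rec(obs), "code", {"http://loinc.org"}) is Outcome.FAIL

    def test_local_system_fails(self):
        imm = make_immunization()
        imm["site"] = {"coding": [{"system": "urn:local:partner/pA",
                                   "code": "LEFTARM"}]}
        out = eval_code_conformance(
            _rec(imm), "site",
            {"http://terminology.hl7.org/CodeSystem/v3-ActSite"})
        assert out is Outcome.FAIL

    def test_missing_element_fails(self):
        assert eval_code_conformance(
            _rec(make_patient()), "maritalStatus", {SNOMED}) is Outcome.FAIL

    def test_value_set_membership_enforced(self):
        imm = make_immunization()
        imm["site"] = {"coding": [{
            "system": "http://terminology.hl7.org/CodeSystem/v3-ActSite",
            "code": "XX"}]}
        out = eval_code_conformance(
            _rec(imm), "site",
            {"http://terminology.hl7.org/CodeSystem/v3-ActSite"},
            allowed_codes={"LA", "RA"})
        assert out is Outcome.FAIL


class TestTemporalPlausibility:
    patient = None

    def setup_method(self):
        self.patient = _rec(make_patient(birthDate="1980-05-01"))

    def test_event_before_birth_fails(self):
        cond = make_condition()
        cond["onsetDateTime"] = "1980-04-30"
        out = eval_temporal_plausibility(_rec(cond), self.patient, "after_birth")
        assert out is Outcome.FAIL

    def test_event_on_birth_date_passes(self):
        cond = make_condition()
        cond["onsetDateTime"] = "1980-05-01"
        out = eval_temporal_plausibility(_rec(cond), self.patient, "after_birth")
        assert out is Outcome.PASS

    def test_future_event_fails(self):
        out = eval_temporal_plausibility(
            _rec(make_observation()), self.patient, "not_future",
            query_date=dt.date(2021, 1, 1))
        assert out is Outcome.FAIL  # observed 2021-03-02

    def test_missing_operand_not_applicable(self):
        cond = make_condition()
        del cond["onsetDateTime"]
        out = eval_temporal_plausibility(_rec(cond), self.patient, "after_birth")
        assert out is Outcome.NOT_APPLICABLE

    @pytest.mark.parametrize("onset,abatement,expected", [
        # exhaustive orderings of two dates: only onset <= abatement passes
        ("2021-02-01", "2021-03-01", Outcome.PASS),
        ("2021-03-01", "2021-03-01", Outcome.PASS),
        ("2021-03-01", "2021-02-01", Outcome.FAIL),
    ])
    def test_onset_abatement_orderings(self, onset, abatement, expected):
        cond = make_condition()
        cond["onsetDateTime"] = onset
        cond["abatementDateTime"] = abatement
        out = eval_temporal_plausibility(
            _rec(cond), self.patient, "onset_before_abatement")
        assert out is expected


def _partner_case(resources, partner="pA"):
    case = PatientCase(partner, "p1", WINDOW, resources=resources)
    case.query_date = dt.date(2023, 6, 1)
    return case


def _lot_test():
    for t in register_builtin_tests():
        if t.test_id == "immunization_lot_number":
            return t
    raise LookupError


class TestRunTest:
    def test_three_of_four_pass(self):
        recs = [_rec(make_immunization(rid=f"i{k}", lotNumber="L1"))
                for k in range(3)]
        recs.append(_rec(make_immunization(rid="i4")))
        result = run_test(_lot_test(), [_partner_case(recs)])
        assert (result.n_applicable, result.n_pass) == (4, 3)
        assert result.pct_pass == 75.0

    def test_zero_applicable_gives_na(self):
        result = run_test(_lot_test(), [_partner_case([_rec(make_patient())])])
        assert result.n_applicable == 0 and result.pct_pass is None

    def test_all_pass_is_100(self):
        recs = [_rec(make_immunization(rid=f"i{k}", lotNumber="L"))
                for k in range(5)]
        assert run_test(_lot_test(), [_partner_case(recs)]).pct_pass == 100.0

    def test_irrelevant_records_not_counted(self):
        recs = [_rec(make_immunization(rid="ok", lotNumber="L")),
                _rec(make_immunization(rid="bad", status="entered-in-error"))]
        result = run_test(_lot_test(), [_partner_case(recs)])
        assert result.n_applicable == 1

    def test_inapplicable_records_never_change_pct(self):
        recs = [_rec(make_immunization(rid=f"i{k}", lotNumber="L"))
                for k in range(3)]
        base = run_test(_lot_test(), [_partner_case(recs)])
        noisy = recs + [_rec(make_observation(rid=f"o{k}")) for k in range(10)]
        again = run_test(_lot_test(), [_partner_case(noisy)])
        assert (base.n_applicable, base.n_pass) == (again.n_applicable, again.n_pass)

    def test_mixed_partners_rejected(self):
        cases = [_partner_case([], "pA"), _partner_case([], "pB")]
        with pytest.raises(ValueError):
            run_test(_lot_test(), cases)


class TestRunSuite:
    @staticmethod
    def _suite_for(pcts):
        """Partners with lot-number pass fractions matching `pcts`."""
        by_partner = {}
        for i, pct in enumerate(pcts):
            recs = []
            n = 10
            n_ok = round(n * pct / 100)
            for k in range(n):
                kwargs = {"lotNumber": "L"} if k < n_ok else {}
                recs.append(record_from_resource(
                    make_immunization(rid=f"i{k}", **kwargs), f"p{i}", "p1"))
            by_partner[f"p{i}"] = [_partner_case(recs, f"p{i}")]
        reg = Registry([_lot_test()])
        return run_suite(reg, by_partner)

    def test_across_partner_average(self):
        suite = self._suite_for([60.0, 80.0, 100.0])
        assert suite.average_pct("immunization_lot_number") == 80.0

    def test_na_partner_skipped_in_average(self):
        by_partner = {
            "p0": [_partner_case([_rec(make_patient())], "p0")],  # no immunizations
            "p1": [_partner_case(
                [record_from_resource(make_immunization(rid="a", lotNumber="L"),
                                      "p1", "p1"),
                 record_from_resource(make_immunization(rid="b"), "p1", "p1")],
                "p1")],
            "p2": [_partner_case(
                [record_from_resource(make_immunization(rid="c", lotNumber="L"),
                                      "p2", "p1")], "p2")],
        }
        suite = run_suite(Registry([_lot_test()]), by_partner)
        assert suite.pct("immunization_lot_number", "p0") is None
        assert suite.average_pct("immunization_lot_number") == 75.0

    def test_defect_free_corpus_all_100(self, clean_corpus):
        cases = clean_corpus.to_cases()
        by_partner = defaultdict(list)
        for c in cases:
            by_partner[c.partner_id].append(c)
        suite = run_suite(register_builtin_tests(), by_partner)
        bad = [k for k, r in suite.results.items()
               if r.pct_pass not in (None, 100.0)]
        assert bad == []


class TestRegistryAccounting:
    def test_duplicate_id_rejected(self):
        reg = Registry()
        reg.add(_lot_test())
        with pytest.raises(RegistrationError):
            reg.add(_lot_test())

    def test_builtin_has_required_lot_number_completeness(self):
        reg = register_builtin_tests()
        t = next(t for t in reg if t.test_id == "immunization_lot_number")
        assert t.category is Category.COMPLETENESS
        assert t.priority is Priority.VAERS_REQUIRED

    def test_builtin_has_after_birth_plausibility(self):
        reg = register_builtin_tests()
        ids = {t.test_id for t in reg}
        assert "condition_onset_after_birth" in ids
        assert "immunization_after_birth" in ids

    def test_accounting_identity_for_builtin_registry(self):
        reg = register_builtin_tests()
        matrix = reg.accounting_matrix()
        totals = manifest_totals({
            (p.value, c.value): n for (p, c), n in matrix.items()})
        assert sum(totals["by_priority"].values()) == totals["total"] == len(reg)
        assert sum(totals["by_category"].values()) == totals["total"]

    def test_study_manifest_shape(self):
        totals = manifest_totals(STUDY_REGISTRY_MANIFEST)
        assert totals["total"] == sum(STUDY_REGISTRY_MANIFEST.values())
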