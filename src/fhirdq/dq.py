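"""Categorized data-quality test registry and execution engine.

Tests follow the Kahn harmonized EHR data-quality framework — completeness
(are values present?), conformance (do values adhere to standard code
systems and value sets?) and plausibility (are values believable?) — and
each carries a priority reflecting the VAERS reporting form: fields the
form marks essential ("VAERS Required"), fields filling any other box
("VAERS Optional"), and elements clinicians flag as useful for AE review
("Helpful").

A test is evaluated per resource: the reported statistic is the percentage
of applicable resources fulfilling the test criteria, computed per partner
and averaged across partners.  Patient-level tests treat each Patient
resource as one applicable record.
"""

from __future__ import annotations

import datetime as _dt
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Callable, Iterable, Mapping, Sequence

from ._util import maybe_date, round_half_up
from . import vocab
from .cases import STUDY_END, PatientCase
from .records import ResourceRecord, Subcategory, get_path
from .relevance import RelevancePolicy, is_semantically_relevant


class Category(str, Enum):
    COMPLETENESS = "completeness"
    CONFORMANCE = "conformance"
    PLAUSIBILITY = "plausibility"


class Priority(str, Enum):
    VAERS_REQUIRED = "vaers_required"
    VAERS_OPTIONAL = "vaers_optional"
    HELPFUL = "helpful"


class Outcome(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_APPLICABLE = "not_applicable"


@dataclass
class CaseContext:
    """Per-case evaluation context shared by all predicates."""

    patient: ResourceRecord | None
    query_date: _dt.date
    n_patients: int
    case: PatientCase | None = None

    @property
    def birth_date(self) -> _dt.date | None:
        if self.patient is None:
            return None
        return maybe_date(self.patient.element("birthDate"))


# --- element-level evaluators ------------------------------------------------

def _is_empty(value: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, str):
        return not value.strip()
    if isinstance(value, (list, dict)):
        if not value:
            return True
        if isinstance(value, list):
            return all(_is_empty(v) for v in value)
    return False


def eval_completeness(
    record: ResourceRecord,
    element_path: str,
    applicable_if: Callable[[ResourceRecord], bool] | None = None,
) -> Outcome:
    """Is the element present with a non-empty recorded value?

    Empty text, whitespace-only text and empty lists count as missing; a
    recorded ``false`` counts as present (it is a value).  ``applicable_if``
    narrows scope (e.g. death date only for deceased patients).
    """
    if applicable_if is not None and not applicable_if(record):
        return Outcome.NOT_APPLICABLE
    value = record.element(element_path)
    return Outcome.FAIL if _is_empty(value) else Outcome.PASS


def _codings_at(record: ResourceRecord, element_path: str) -> list[Mapping]:
    node = get_path(record.raw, element_path)
    if node is None:
        return []
    nodes = node if isinstance(node, list) else [node]
    codings: list[Mapping] = []
    for n in nodes:
        if not isinstance(n, Mapping):
            continue
        if "coding" in n:
            for c in n.get("coding") or []:
                if isinstance(c, Mapping):
                    codings.append(c)
        elif "system" in n or "code" in n:
            codings.append(n)
    return codings


def eval_code_conformance(
    record: ResourceRecord,
    element_path: str,
    allowed_systems: Iterable[str],
    forbid_zero: bool = True,
    allowed_codes: Iterable[str] | None = None,
) -> Outcome:
    """Does the element carry a code from an interoperable code system?

    Passes iff some coding at the path uses an allowed system URI with a
    non-empty code, the code is not the invalid placeholder "0" (when
    ``forbid_zero``), and — when ``allowed_codes`` is given — the code is a
    member of that value set.  Locally-defined systems fail; a missing
    element fails (the resource is not interoperably coded).
    """
    allowed = set(allowed_systems)
    if not allowed:
        raise ValueError("allowed_systems must be non-empty")
    for coding in _codings_at(record, element_path):
        system, code = coding.get("system"), coding.get("code")
        if system not in allowed:
            continue
        if _is_empty(code):
            continue
        if forbid_zero and str(code).strip() == "0":
            continue
        if allowed_codes is not None and str(code) not in set(allowed_codes):
            continue
        return Outcome.PASS
    return Outcome.FAIL


def _event_start(record: ResourceRecord) -> _dt.date | None:
    ev = record.event_date
    if isinstance(ev, tuple):
        return ev[0]
    return ev


def eval_temporal_plausibility(
    record: ResourceRecord,
    patient: ResourceRecord | None,
    rule: str,
    query_date: _dt.date | None = None,
) -> Outcome:
    """Temporal believability rules.

    ``after_birth``: the event date falls on or after the patient's birth
    date (same-day events pass — birth-day care is clinically valid).
    ``not_future``: the event date falls on or before the query date.
    ``onset_before_abatement``: condition onset <= abatement when both exist.
    A missing operand makes the rule not applicable.
    """
    if rule == "after_birth":
        birth = maybe_date(patient.element("birthDate")) if patient else None
        event = _event_start(record)
        if birth is None or event is None:
            return Outcome.NOT_APPLICABLE
        return Outcome.PASS if event >= birth else Outcome.FAIL
    if rule == "not_future":
        event = _event_start(record)
        if event is None or query_date is None:
            return Outcome.NOT_APPLICABLE
        return Outcome.PASS if event <= query_date else Outcome.FAIL
    if rule == "onset_before_abatement":
        onset = maybe_date(record.element("onsetDateTime"))
        abatement = maybe_date(record.element("abatementDateTime"))
        if onset is None or abatement is None:
            return Outcome.NOT_APPLICABLE
        return Outcome.PASS if onset <= abatement else Outcome.FAIL
    raise ValueError(f"unknown plausibility rule: {rule!r}")


# --- test registry -----------------------------------------------------------

Predicate = Callable[[ResourceRecord, CaseContext], Outcome]
Selector = Callable[[ResourceRecord, CaseContext], bool]


@dataclass
class DQTest:
    test_id: str
    label: str
    category: Category
    priority: Priority
    applicability: Selector
    evaluate: Predicate
    vaers_line: int | None = None
    standards_ref: str | None = None
    root_causes: list[str] = field(default_factory=list)


class RegistrationError(ValueError):
    pass


@dataclass
class TestRegistry:
    tests: list[DQTest] = field(default_factory=list)

    def add(self, test: DQTest) -> None:
        if any(t.test_id == test.test_id for t in self.tests):
            raise RegistrationError(f"duplicate test_id {test.test_id!r}")
        self.tests.append(test)

    def __iter__(self):
        return iter(self.tests)

    def __len__(self):
        return len(self.tests)

    def accounting_matrix(self) -> dict[tuple[Priority, Category], int]:
        """Count of tests per (priority, category) cell."""
        matrix = {(p, c): 0 for p in Priority for c in Category}
        for t in self.tests:
            matrix[(t.priority, t.category)] += 1
        return matrix


def _scope_type(rtype: str, extra: Selector | None = None) -> Selector:
    def sel(record: ResourceRecord, ctx: CaseContext) -> bool:
        if record.resource_type != rtype:
            return False
        return extra(record, ctx) if extra else True

    return sel


def _scope_sub(sub: Subcategory, extra: Selector | None = None) -> Selector:
    def sel(record: ResourceRecord, ctx: CaseContext) -> bool:
        if record.subcategory != sub:
            return False
        return extra(record, ctx) if extra else True

    return sel


def _completeness(path: str) -> Predicate:
    def pred(record: ResourceRecord, ctx: CaseContext) -> Outcome:
        return eval_completeness(record, path)

    return pred


def _any_complete(*paths: str) -> Predicate:
    def pred(record: ResourceRecord, ctx: CaseContext) -> Outcome:
        for p in paths:
            if eval_completeness(record, p) is Outcome.PASS:
                return Outcome.PASS
        return Outcome.FAIL

    return pred


def _conformance(path: str, systems, codes=None) -> Predicate:
    def pred(record: ResourceRecord, ctx: CaseContext) -> Outcome:
        return eval_code_conformance(record, path, systems, allowed_codes=codes)

    return pred


def _temporal(rule: str) -> Predicate:
    def pred(record: ResourceRecord, ctx: CaseContext) -> Outcome:
        return eval_temporal_plausibility(record, ctx.patient, rule, ctx.query_date)

    return pred


def _deceased(record: ResourceRecord) -> bool:
    return record.element("deceasedBoolean") is True or record.element(
        "deceasedDateTime"
    ) is not None


def register_builtin_tests() -> TestRegistry:
    """The built-in data-quality test registry.

    Implements every named test family from the adverse-event review test
    battery: immunization detail completeness, condition and encounter
    dates and references, patient demographics and death data, clinical
    note retrieval, code-system conformance (CVX / SNOMED CT / ICD-10-CM /
    LOINC / RxNorm), VAERS site and route value sets, and temporal and
    uniqueness plausibility.  Extensible: construct more ``DQTest`` objects
    and ``add`` them.
    """
    R, O, H = Priority.VAERS_REQUIRED, Priority.VAERS_OPTIONAL, Priority.HELPFUL
    CMP, CNF, PLS = Category.COMPLETENESS, Category.CONFORMANCE, Category.PLAUSIBILITY
    reg = TestRegistry()

    def add(test_id, label, cat, pri, scope, pred, line=None, ref=None):
        reg.add(DQTest(test_id, label, cat, pri, scope, pred, line, ref))

    pt = _scope_type("Patient")
    imm = _scope_type("Immunization")
    enc = _scope_type("Encounter")
    cond_dx = _scope_sub(Subcategory.CONDITION_ENCOUNTER_DIAGNOSIS)
    cond_prob = _scope_sub(Subcategory.CONDITION_PROBLEM_HEALTH_CONCERN)
    note = _scope_sub(Subcategory.DOCREF_CLINICAL_NOTE)
    lab = _scope_sub(Subcategory.OBS_LAB_TEST)
    allergy = _scope_type("AllergyIntolerance")
    medreq = _scope_type("MedicationRequest")
    proc = _scope_type("Procedure")
    pract = _scope_type("Practitioner")
    loc = _scope_type("Location")

    # ---- VAERS Required / completeness ----
    add("patient_name", "Patient name recorded", CMP, R, pt, _completeness("name"), 1,
        "Patient.name")
    add("patient_birth_date", "Patient date of birth recorded", CMP, R, pt,
        _completeness("birthDate"), 2, "Patient.birthDate")
    add("patient_gender", "Patient sex recorded", CMP, R, pt,
        _completeness("gender"), 3, "Patient.gender")
    add("patient_address", "Patient address recorded", CMP, R, pt,
        _completeness("address"), 4, "Patient.address")
    add("condition_encdx_dates",
        "Condition encounter diagnosis recorded, onset and encounter date", CMP, R,
        cond_dx, _any_complete("onsetDateTime", "recordedDate"), 5,
        "Condition.onset")
    add("immunization_date", "Immunization administration date recorded", CMP, R, imm,
        _completeness("occurrenceDateTime"), 17, "Immunization.occurrenceDateTime")
    add("immunization_vaccine_code", "Immunization vaccine code recorded", CMP, R, imm,
        _completeness("vaccineCode"), 17, "Immunization.vaccineCode")
    add("immunization_lot_number", "Immunization lot number recorded", CMP, R, imm,
        _completeness("lotNumber"), 17, "Immunization.lotNumber")
    add("immunization_manufacturer", "Immunization manufacturer recorded", CMP, R, imm,
        _completeness("manufacturer"), 17, "Immunization.manufacturer")
    add("immunization_site", "Immunization body site recorded", CMP, R, imm,
        _completeness("site"), 17, "Immunization.site")
    add("immunization_route", "Immunization route recorded", CMP, R, imm,
        _completeness("route"), 17, "Immunization.route")
    add("immunization_dose_number", "Immunization dose number in series recorded",
        CMP, R, imm, _completeness("protocolApplied.doseNumberPositiveInt"), 17,
        "Immunization.protocolApplied.doseNumber")
    add("encounter_diagnosis", "Encounter diagnosis list populated", CMP, R, enc,
        _completeness("diagnosis"), 18, "Encounter.diagnosis")
    add("docref_note_data", "Clinical note data successfully retrieved", CMP, R, note,
        _any_complete("content.attachment.data", "content.attachment.url"), 18,
        "DocumentReference.content")
    add("docref_note_date", "Clinical note date or period recorded", CMP, R, note,
        _any_complete("date", "context.period"), 18, "DocumentReference.date")
    add("procedure_performed_date", "Procedure performed date recorded", CMP, R, proc,
        _any_complete("performedDateTime", "performedPeriod"), 18,
        "Procedure.performedDateTime")
    add("patient_deceased_indicator", "Patient deceased indicator recorded", CMP, R, pt,
        _any_complete("deceasedBoolean", "deceasedDateTime"), 21,
        "Patient.deceasedBoolean")
    add("patient_deceased_date", "Patient death date recorded (deceased patients)",
        CMP, R, _scope_type("Patient", lambda r, c: _deceased(r)),
        _completeness("deceasedDateTime"), 21, "Patient.deceasedDateTime")

    # ---- VAERS Required / conformance ----
    add("immunization_cvx", "Immunization vaccine code uses CVX", CNF, R, imm,
        _conformance("vaccineCode", vocab.ALLOWED_SYSTEMS["immunization_vaccine"]),
        17, "Immunization.vaccineCode.system")
    add("immunization_site_value_set", "Immunization site uses the standard value set",
        CNF, R, imm,
        _conformance("site", {vocab.SITE_SYSTEM}, codes=vocab.SITE_VALUE_SET),
        17, "Immunization.site.valueset")
    add("immunization_route_value_set",
        "Immunization route uses the standard value set", CNF, R, imm,
        _conformance("route", {vocab.ROUTE_SYSTEM}, codes=vocab.ROUTE_VALUE_SET),
        17, "Immunization.route.valueset")
    add("condition_encdx_code_system",
        "Condition encounter diagnosis coded in SNOMED CT or ICD-10-CM", CNF, R,
        cond_dx, _conformance("code", vocab.ALLOWED_SYSTEMS["condition_code"]), 18,
        "Condition.code.system")
    add("docref_type_loinc", "DocumentReference type coded in LOINC", CNF, R,
        _scope_type("DocumentReference"),
        _conformance("type", vocab.ALLOWED_SYSTEMS["docref_type"]), 18,
        "DocumentReference.type.system")

    # ---- VAERS Required / plausibility ----
    add("immunization_after_birth", "Immunization date on/after patient birth date",
        PLS, R, imm, _temporal("after_birth"), 17, "Immunization.occurrenceDateTime")
    add("immunization_not_future", "Immunization date on/before query date", PLS, R,
        imm, _temporal("not_future"), 17, "Immunization.occurrenceDateTime")
    add("condition_onset_after_birth", "AE condition onset on/after patient birth date",
        PLS, R, cond_dx, _temporal("after_birth"), 5, "Condition.onset")
    add("condition_onset_not_future", "AE condition onset on/before query date", PLS,
        R, cond_dx, _temporal("not_future"), 5, "Condition.onset")
    add("condition_encdx_valid_encounter_ref",
        "Condition encounter diagnosis valid encounter reference", PLS, R,
        _scope_sub(Subcategory.CONDITION_ENCOUNTER_DIAGNOSIS,
                   lambda r, c: r.element("encounter") is not None),
        _valid_encounter_ref, 18, "Encounter.diagnosis")
    add("patient_unique_per_case", "Exactly one patient resource per case", PLS, R, pt,
        lambda r, c: Outcome.PASS if c.n_patients == 1 else Outcome.FAIL, 2,
        "Patient")
    add("deceased_date_after_birth", "Death date on/after birth date", PLS, R,
        _scope_type("Patient", lambda r, c: r.element("deceasedDateTime") is not None),
        lambda r, c: _compare_dates(r.element("deceasedDateTime"),
                                    r.element("birthDate")), 21,
        "Patient.deceasedDateTime")

    # ---- VAERS Optional ----
    add("patient_country", "Patient address country recorded", CMP, O, pt,
        _completeness("address.country"), 1, "Patient.address.country")
    add("patient_race", "Patient race recorded", CMP, O, pt,
        _race_ethnicity_pred("us-core-race"), 12, "Patient.race")
    add("patient_ethnicity", "Patient ethnicity recorded", CMP, O, pt,
        _race_ethnicity_pred("us-core-ethnicity"), 25, "Patient.ethnicity")
    add("allergy_recorded", "Allergy code recorded", CMP, O, allergy,
        _completeness("code"), 8, "AllergyIntolerance.code")
    add("medication_request_presence",
        "Medications at time of vaccination present", CMP, O, medreq,
        _any_complete("medicationCodeableConcept", "medicationReference"), 9,
        "MedicationRequest.medication")
    add("condition_problem_code", "Condition problem/health concern code recorded",
        CMP, O, cond_prob, _completeness("code"), 11, "Condition.code")
    add("diagnostic_report_code", "Diagnostic report code recorded", CMP, O,
        _scope_type("DiagnosticReport"), _completeness("code"), 18,
        "DiagnosticReport.code")
    add("practitioner_contact", "Treating practitioner contact information", CMP, O,
        pract, _any_complete("telecom", "address"), 14, "Practitioner.telecom")
    add("location_contact", "Facility contact information", CMP, O, loc,
        _any_complete("telecom", "address"), 15, "Location.telecom")
    add("location_site_type", "Facility site type recorded", CMP, O, loc,
        _completeness("type"), 15, "Location.type")
    add("condition_asserter", "Condition asserter recorded", CMP, O,
        _scope_type("Condition"), _completeness("asserter"), 14, "Condition.asserter")
    add("condition_abatement_date", "AE condition abatement date recorded", CMP, O,
        cond_dx, _completeness("abatementDateTime"), 20, "Condition.abatement")
    add("immunization_reaction", "Immunization reaction details recorded", CMP, O, imm,
        _completeness("reaction"), 23, "Immunization.reaction")
    add("immunization_reaction_date", "Immunization reaction date recorded", CMP, O,
        _scope_type("Immunization", lambda r, c: r.element("reaction") is not None),
        _completeness("reaction.date"), 23, "Immunization.reaction.date")
    add("patient_veteran_status", "Patient veteran status recorded", CMP, O, pt,
        _extension_pred("us-veteran-status"), 27, "Patient.veteranStatus")
    add("allergy_code_system", "Allergy coded in SNOMED CT or RxNorm", CNF, O, allergy,
        _conformance("code", vocab.ALLOWED_SYSTEMS["allergy_code"]), 8,
        "AllergyIntolerance.code.system")
    add("obs_lab_loinc", "Lab test coded in LOINC", CNF, O, lab,
        _conformance("code", vocab.ALLOWED_SYSTEMS["observation_lab_code"]), 18,
        "Observation.code.system")
    add("medication_rxnorm", "Medication coded in RxNorm", CNF, O, medreq,
        _medication_rxnorm, 9, "MedicationRequest.medication.system")
    add("onset_before_abatement", "Condition onset on/before abatement", PLS, O,
        _scope_type("Condition"), _temporal("onset_before_abatement"), 20,
        "Condition.abatement")
    add("condition_problem_onset_after_birth",
        "Problem onset on/after patient birth date", PLS, O, cond_prob,
        _temporal("after_birth"), 11, "Condition.onset")

    # ---- Helpful ----
    add("allergy_onset_date", "Allergy onset date recorded", CMP, H, allergy,
        _any_complete("onsetDateTime", "recordedDate"), None,
        "AllergyIntolerance.onset")
    add("immunization_dose_quantity", "Immunization dose quantity recorded", CMP, H,
        imm, _completeness("doseQuantity"), None, "Immunization.doseQuantity")
    add("encounter_period", "Encounter period recorded", CMP, H, enc,
        _completeness("period"), None, "Encounter.period")
    add("encounter_class", "Encounter class recorded", CMP, H, enc,
        _completeness("class"), None, "Encounter.class")
    add("observation_value", "Observation value recorded", CMP, H,
        _scope_type("Observation"),
        _any_complete("valueQuantity", "valueCodeableConcept", "valueString"), None,
        "Observation.value")
    add("medication_authored_on", "Medication request authored date recorded", CMP, H,
        medreq, _completeness("authoredOn"), None, "MedicationRequest.authoredOn")
    add("encounter_class_conformant", "Encounter class uses the ActCode system", CNF,
        H, enc, _conformance(
            "class", {"http://terminology.hl7.org/CodeSystem/v3-ActCode"}), None,
        "Encounter.class.system")
    add("observation_date_after_birth", "Observation date on/after birth date", PLS,
        H, _scope_type("Observation"), _temporal("after_birth"), None,
        "Observation.effective")
    add("observation_date_not_future", "Observation date on/before query date", PLS,
        H, _scope_type("Observation"), _temporal("not_future"), None,
        "Observation.effective")
    add("encounter_date_not_future", "Encounter start on/before query date", PLS, H,
        enc, _temporal("not_future"), None, "Encounter.period")
    return reg


def _medication_rxnorm(record: ResourceRecord, ctx: CaseContext) -> Outcome:
    """RxNorm conformance, following medicationReference when needed."""
    if record.element("medicationCodeableConcept") is not None:
        return eval_code_conformance(
            record, "medicationCodeableConcept",
            vocab.ALLOWED_SYSTEMS["medication_code"])
    ref_ids = {r.target_id for r in record.references if r.target_type == "Medication"}
    if ref_ids and ctx.case is not None:
        for res in ctx.case.resources:
            if res.resource_type == "Medication" and res.resource_id in ref_ids:
                return eval_code_conformance(
                    res, "code", vocab.ALLOWED_SYSTEMS["medication_code"])
    return Outcome.FAIL


def _valid_encounter_ref(record: ResourceRecord, ctx: CaseContext) -> Outcome:
    """The AE condition's encounter reference resolves within the case."""
    if ctx.case is None:
        return Outcome.NOT_APPLICABLE
    targets = {
        r.resource_id for r in ctx.case.resources if r.resource_type == "Encounter"
    }
    for ref in record.references:
        if ref.target_type == "Encounter":
            return Outcome.PASS if ref.target_id in targets else Outcome.FAIL
    return Outcome.NOT_APPLICABLE


def _compare_dates(later, earlier) -> Outcome:
    d1, d0 = maybe_date(later), maybe_date(earlier)
    if d1 is None or d0 is None:
        return Outcome.NOT_APPLICABLE
    return Outcome.PASS if d1 >= d0 else Outcome.FAIL


def _race_ethnicity_pred(ext_suffix: str) -> Predicate:
    def pred(record: ResourceRecord, ctx: CaseContext) -> Outcome:
        for ext in record.raw.get("extension", []) or []:
            url = ext.get("url", "")
            if url.endswith(ext_suffix):
                return Outcome.PASS if not _is_empty(
                    ext.get("extension") or ext.get("valueCoding")
                    or ext.get("valueString")
                ) else Outcome.FAIL
        return Outcome.FAIL

    return pred


def _extension_pred(ext_suffix: str) -> Predicate:
    def pred(record: ResourceRecord, ctx: CaseContext) -> Outcome:
        for ext in record.raw.get("extension", []) or []:
            if ext.get("url", "").endswith(ext_suffix):
                return Outcome.PASS
        return Outcome.FAIL

    return pred


# --- execution ---------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    test_id: str
    partner_id: str
    n_applicable: int
    n_pass: int

    @property
    def pct_pass(self) -> float | None:
        if self.n_applicable == 0:
            return None
        return round_half_up(100.0 * self.n_pass / self.n_applicable, 1)


def _case_context(case: PatientCase) -> CaseContext:
    patients = [r for r in case.resources if r.resource_type == "Patient"]
    return CaseContext(
        patient=patients[0] if patients else None,
        query_date=case.query_date or STUDY_END,
        n_patients=len(patients),
        case=case,
    )


def run_test(
    test: DQTest,
    cases: Sequence[PatientCase],
    policy: RelevancePolicy | None = None,
) -> TestResult:
    """Evaluate one test over one partner's cases.

    The denominator is applicable *resources*; only semantically-relevant
    records are considered (status-negated resources are missing data by
    design and would distort the profile).
    """
    partners = {c.partner_id for c in cases}
    if len(partners) > 1:
        raise ValueError("run_test expects cases from a single partner")
    policy = policy or RelevancePolicy()
    n_applicable = n_pass = 0
    for case in cases:
        ctx = _case_context(case)
        for rec in case.resources:
            if not is_semantically_relevant(rec, policy):
                continue
            if not test.applicability(rec, ctx):
                continue
            outcome = test.evaluate(rec, ctx)
            if outcome is Outcome.NOT_APPLICABLE:
                continue
            n_applicable += 1
            if outcome is Outcome.PASS:
                n_pass += 1
    return TestResult(test.test_id, partners.pop() if partners else "", n_applicable, n_pass)


@dataclass
class SuiteResult:
    """Full test x partner result matrix with across-partner averages."""

    results: dict[tuple[str, str], TestResult]  # (test_id, partner_id) -> result
    test_ids: list[str]
    partner_ids: list[str]

    def pct(self, test_id: str, partner_id: str) -> float | None:
        res = self.results.get((test_id, partner_id))
        return res.pct_pass if res else None

    def partner_pcts(self, test_id: str) -> dict[str, float | None]:
        return {p: self.pct(test_id, p) for p in self.partner_ids}

    def average_pct(self, test_id: str) -> float | None:
        """Across-partner mean of pct_pass, over partners with applicable data."""
        vals = [v for v in self.partner_pcts(test_id).values() if v is not None]
        if not vals:
            return None
        return round_half_up(sum(vals) / len(vals), 1)

    def to_long_table(self):
        """Long-format results — the strip-plot data contract."""
        import pandas as pd

        rows = []
        for (tid, pid), res in sorted(self.results.items()):
            rows.append({
                "test_id": tid,
                "partner_id": pid,
                "n_applicable": res.n_applicable,
                "n_pass": res.n_pass,
                "pct_pass": res.pct_pass,
            })
        return pd.DataFrame(rows)


def run_suite(
    registry: TestRegistry | Iterable[DQTest],
    cases_by_partner: Mapping[str, Sequence[PatientCase]],
    policy: RelevancePolicy | None = None,
) -> SuiteResult:
    """Evaluate every registry test for every partner; deterministic."""
    if not cases_by_partner:
        raise ValueError("at least one partner required")
    tests = list(registry)
    results: dict[tuple[str, str], TestResult] = {}
    for partner_id in sorted(cases_by_partner):
        cases = cases_by_partner[partner_id]
        for test in tests:
            res = run_test(test, cases, policy)
            results[(test.test_id, partner_id)] = TestResult(
                test.test_id, partner_id, res.n_applicable, res.n_pass
            )
    return SuiteResult(
        results=results,
        test_ids=[t.test_id for t in tests],
        partner_ids=sorted(cases_by_partner),
    )


# --- study registry manifest -------------------------------------------------

#: Declared accounting of the full assessment registry: tests per
#: (priority, category) cell.  The complete test battery is site
#: configuration; this manifest records its declared shape so registry
#: accounting identities can be checked and reported.
STUDY_REGISTRY_MANIFEST: dict[tuple[str, str], int] = {
    ("vaers_required", "completeness"): 21,
    ("vaers_required", "conformance"): 8,
    ("vaers_required", "plausibility"): 10,
    ("vaers_optional", "completeness"): 44,
    ("vaers_optional", "conformance"): 7,
    ("vaers_optional", "plausibility"): 21,
    ("helpful", "completeness"): 112,
    ("helpful", "conformance"): 41,
    ("helpful", "plausibility"): 66,
}


def manifest_totals(
    manifest: Mapping[tuple[str, str], int] | None = None,
) -> dict[str, Any]:
    """Row, column and grand totals of an accounting matrix.

    The accounting identity — row sums and column sums each summing to the
    same grand total — must hold for any well-formed registry manifest.
    """
    manifest = STUDY_REGISTRY_MANIFEST if manifest is None else manifest
    row_totals: dict[str, int] = defaultdict(int)
    col_totals: dict[str, int] = defaultdict(int)
    for (pri, cat), n in manifest.items():
        pri = pri.value if isinstance(pri, Priority) else pri
        cat = cat.value if isinstance(cat, Category) else cat
        row_totals[pri] += n
        col_totals[cat] += n
    grand = sum(manifest.values())
    assert sum(row_totals.values()) == sum(col_totals.values()) == grand
    return {
        "by_priority": dict(row_totals),
        "by_category": dict(col_totals),
        "total": grand,
    }
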