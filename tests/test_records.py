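"""FHIR ingestion, subcategory classification and reference extraction."""

from __future__ import annotations

import json

import pytest

from fhirdq.records import (
    NON_CLINICAL_SUBCATEGORIES, ParseError, Reference, Subcategory,
    classify_subcategory, extract_references, read_resources,
    record_from_resource, serialized_size,
)

from conftest import (
    bundle_of, make_condition, make_immunization, make_observation, make_patient,
)


class TestReadResources:
    def test_bundle_count_and_types_preserved(self):
        records = read_resources(
            bundle_of(make_patient(), make_immunization()), "pA")
        assert [r.resource_type for r in records] == ["Patient", "Immunization"]

    def test_empty_bundle(self):
        assert read_resources(bundle_of(), "pA") == []

    def test_ndjson_stream(self, tmp_path):
        path = tmp_path / "obs.ndjson"
        path.write_text("\n".join(
            json.dumps(make_observation(rid=f"o{i}")) for i in range(3)))
        records = read_resources(path, "pA")
        assert len(records) == 3
        assert all(r.resource_type == "Observation" for r in records)

    def test_missing_discriminator_names_entry(self):
        bad = bundle_of(make_patient(), {"id": "x"})
        with pytest.raises(ParseError, match="entry 1"):
            read_resources(bad, "pA")

    def test_empty_partner_rejected(self):
        with pytest.raises(ValueError):
            read_resources(bundle_of(), "")

    def test_roundtrip_preserves_normalized_fields(self):
        rec = record_from_resource(make_condition(), "pA", "p1")
        again = record_from_resource(json.loads(json.dumps(rec.raw)), "pA", "p1")
        assert (rec.resource_type, rec.subcategory, rec.status,
                rec.primary_code, rec.event_date) == (
            again.resource_type, again.subcategory, again.status,
            again.primary_code, again.event_date)


class TestClassification:
    @pytest.mark.parametrize("resource,expected", [
        (make_observation(category="laboratory"), Subcategory.OBS_LAB_TEST),
        (make_observation(category="vital-signs"), Subcategory.OBS_VITAL_SIGN),
        (make_observation(category="social-history"), Subcategory.OBS_SOCIAL_HISTORY),
        (make_observation(category="LDA"), Subcategory.OBS_LDA),
        (make_observation(category="survey"), Subcategory.OBS_OTHER),
        (make_condition(category="encounter-diagnosis"),
         Subcategory.CONDITION_ENCOUNTER_DIAGNOSIS),
        (make_condition(category="problem-list-item"),
         Subcategory.CONDITION_PROBLEM_HEALTH_CONCERN),
        ({"resourceType": "Location", "id": "l1"}, Subcategory.AUXILIARY),
        ({"resourceType": "Practitioner", "id": "pr1"}, Subcategory.AUXILIARY),
        (make_patient(), Subcategory.PATIENT),
        ({"resourceType": "Procedure", "id": "pc",
          "category": {"coding": [{"display": "Surgical procedure"}]}},
         Subcategory.PROCEDURE_SURGICAL_HISTORY),
        ({"resourceType": "Procedure", "id": "pc"}, Subcategory.PROCEDURE_ORDER),
    ])
    def test_subcategory_mapping(self, resource, expected):
        assert classify_subcategory(resource) == expected

    @pytest.mark.parametrize("code,expected", [
        ("11506-3", Subcategory.DOCREF_CLINICAL_NOTE),
        ("18748-4", Subcategory.DOCREF_IMAGING_RESULT),
        ("34133-9", Subcategory.DOCREF_EXTERNAL_CDA),
        ("unmapped-code", Subcategory.DOCREF_CLINICAL_NOTE),  # default bucket
    ])
    def test_docref_strata(self, code, expected):
        res = {"resourceType": "DocumentReference", "id": "d1",
               "type": {"coding": [{"system": "http://loinc.org", "code": code}]}}
        assert classify_subcategory(res) == expected

    def test_docref_local_label(self):
        res = {"resourceType": "DocumentReference", "id": "d1",
               "type": {"text": "Correspondence"}}
        assert classify_subcategory(res) == Subcategory.DOCREF_CORRESPONDENCE

    def test_partition_over_synthetic_corpus(self, small_cases):
        """Each non-auxiliary record maps to exactly one clinical stratum."""
        records = [r for c in small_cases for r in c.resources]
        clinical = [r for r in records
                    if r.subcategory not in NON_CLINICAL_SUBCATEGORIES]
        per_sub = {}
        for r in clinical:
            per_sub[r.subcategory] = per_sub.get(r.subcategory, 0) + 1
        assert sum(per_sub.values()) == len(clinical)


class TestReferences:
    def test_encounter_references(self):
        enc = {"resourceType": "Encounter", "id": "e1",
               "location": [{"location": {"reference": "Location/L1"}}],
               "participant": [{"individual": {"reference": "Practitioner/P1"}}]}
        assert extract_references(enc) == {
            Reference("Location", "L1"), Reference("Practitioner", "P1")}

    def test_no_references(self):
        assert extract_references(make_patient()) == set()

    def test_duplicate_references_deduplicated(self):
        mr = {"resourceType": "MedicationRequest", "id": "m1",
              "medicationReference": {"reference": "Medication/M1"},
              "supportingInformation": [{"reference": "Medication/M1"}]}
        assert extract_references(mr) == {Reference("Medication", "M1")}

    def test_self_reference_excluded(self):
        res = {"resourceType": "Patient", "id": "p1",
               "link": [{"other": {"reference": "Patient/p1"}}]}
        assert extract_references(res) == set()


class TestSize:
    def test_size_positive_and_additive(self):
        resources = [make_patient(), make_immunization(), make_observation()]
        bundle = bundle_of(*resources)
        entry_sizes = [serialized_size(r) for r in resources]
        assert all(s > 0 for s in entry_sizes)
        assert sum(entry_sizes) <= serialized_size(bundle)

    def test_size_matches_minified_utf8(self):
        res = make_patient()
        expected = len(json.dumps(res, separators=(",", ":")).encode())
        rec = record_from_resource(res, "pA")
        assert rec.size_bytes == expected
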