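"""Shared fixtures: tiny FHIR objects and reduced synthetic corpora."""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from fhirdq.synth import (  # noqa: E402
    DEFAULT_COMPLETENESS, DEFAULT_LOCAL_RATES, GeneratorConfig, generate_corpus,
)


def make_patient(pid="p1", birth="1980-05-01", **extra):
    res = {"resourceType": "Patient", "id": pid, "birthDate": birth,
           "gender": "female", "name": [{"family": "Doe"}]}
    res.update(extra)
    return res


def make_immunization(pid="p1", rid="imm1", status="completed", **extra):
    res = {
        "resourceType": "Immunization", "id": rid, "status": status,
        "patient": {"reference": f"Patient/{pid}"},
        "vaccineCode": {"coding": [{"system": "http://hl7.org/fhir/sid/cvx",
                                    "code": "208"}]},
        "occurrenceDateTime": "2021-03-01",
    }
    res.update(extra)
    return res


def make_observation(rid="obs1", category="laboratory", **extra):
    res = {
        "resourceType": "Observation", "id": rid, "status": "final",
        "subject": {"reference": "Patient/p1"},
        "category": [{"coding": [{
            "system": "http://terminology.hl7.org/CodeSystem/observation-category",
            "code": category}]}],
        "code": {"coding": [{"system": "http://loinc.org", "code": "718-7"}]},
        "effectiveDateTime": "2021-03-02",
    }
    res.update(extra)
    return res


def make_condition(rid="cond1", category="encounter-diagnosis", **extra):
    res = {
        "resourceType": "Condition", "id": rid,
        "subject": {"reference": "Patient/p1"},
        "category": [{"coding": [{
            "system": "http://terminology.hl7.org/CodeSystem/condition-category",
            "code": category}]}],
        "verificationStatus": {"coding": [{"code": "confirmed"}]},
        "code": {"coding": [{"system": "http://snomed.info/sct",
                             "code": "386661006"}]},
        "onsetDateTime": "2021-03-02",
    }
    res.update(extra)
    return res


def bundle_of(*resources):
    return {"resourceType": "Bundle", "type": "collection",
            "entry": [{"resource": r} for r in resources]}


def defect_free_config(seed=7, **overrides):
    """Generator settings with every plantable defect switched off."""
    params = dict(
        element_completeness={k: 1.0 for k in DEFAULT_COMPLETENESS},
        local_code_rate=0.0,
        local_code_rates={k: 0.0 for k in DEFAULT_LOCAL_RATES},
        irrelevant_status_rate=0.0,
        multiple_match_rate=0.0, no_match_rate=0.0, btg_rate=0.0,
    )
    params.update(overrides)
    return GeneratorConfig.small(seed=seed, **params)


@pytest.fixture(scope="session")
def small_corpus():
    """A reduced corpus with the default defect rates."""
    return generate_corpus(GeneratorConfig.small(seed=11))


@pytest.fixture(scope="session")
def small_cases(small_corpus):
    return small_corpus.to_cases()


@pytest.fixture(scope="session")
def clean_corpus():
    return generate_corpus(defect_free_config(seed=7))
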