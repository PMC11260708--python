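"""Code-system URIs and small sample vocabularies.

The sample code lists are deliberately tiny, synthetic slices of the real
terminologies (CVX, LOINC, SNOMED CT, ICD-10-CM, RxNorm) — enough for the
synthetic generator to draw realistic-looking codes and for conformance
tests to distinguish standard from locally-defined systems.  They are not
exhaustive and must never be used for real terminology validation.
"""

from __future__ import annotations

# Canonical system URIs
CVX = "http://hl7.org/fhir/sid/cvx"
SNOMED = "http://snomed.info/sct"
ICD10CM = "http://hl7.org/fhir/sid/icd-10-cm"
LOINC = "http://loinc.org"
RXNORM = "http://www.nlm.nih.gov/research/umls/rxnorm"
UCUM = "http://unitsofmeasure.org"

#: URI prefix used by the synthetic generator for locally-defined systems,
#: emulating partner-site EHR code systems that are not interoperable.
LOCAL_SYSTEM_PREFIX = "urn:local:partner"

#: Systems accepted by the shipped conformance tests, per tested element.
ALLOWED_SYSTEMS = {
    "immunization_vaccine": {CVX},
    "condition_code": {SNOMED, ICD10CM},
    "observation_lab_code": {LOINC},
    "medication_code": {RXNORM},
    "docref_type": {LOINC},
    "allergy_code": {SNOMED, RXNORM},
}

# --- sample code lists (synthetic, non-exhaustive slices) -------------------

CVX_CODES = ["208", "207", "212", "217", "218", "229", "300", "110", "115", "33"]

SNOMED_CONDITION_CODES = [
    "386661006", "29857009", "25064002", "267036007", "422587007",
    "271807003", "49727002", "68962001", "3424008", "76067001",
]

ICD10_CONDITION_CODES = ["R50.9", "R07.9", "R06.02", "R21", "T88.1", "R51.9"]

LOINC_LAB_CODES = [
    "718-7", "6690-2", "2160-0", "2345-7", "2951-2", "2823-3",
    "1988-5", "30239-8", "42176-8", "2532-0",
]

LOINC_VITAL_CODES = ["8480-6", "8462-4", "8867-4", "8310-5", "9279-1", "59408-5"]

#: LOINC document-type codes by reporting stratum (see records.DOCREF_STRATA).
LOINC_NOTE_CODES = {
    "clinical_note": ["11506-3", "34117-2", "18842-5", "11488-4", "28570-0"],
    "imaging": ["18748-4", "18782-3", "24606-6"],
    "cda": ["34133-9"],
}

RXNORM_CODES = ["198440", "310965", "197361", "855332", "1049683", "313002"]

#: VAERS-style administration site codes (HL7 v3 ActSite subset).
SITE_VALUE_SET = {"LA", "RA", "LD", "RD", "LT", "RT", "LVL", "RVL", "LG", "RG"}
SITE_SYSTEM = "http://terminology.hl7.org/CodeSystem/v3-ActSite"

#: Route of administration codes (NCI Thesaurus subset used by immunization IGs).
ROUTE_VALUE_SET = {"IM", "SC", "ID", "PO", "IN", "NS", "TD"}
ROUTE_SYSTEM = "http://terminology.hl7.org/CodeSystem/v3-RouteOfAdministration"

OBSERVATION_CATEGORY_SYSTEM = (
    "http://terminology.hl7.org/CodeSystem/observation-category"
)
CONDITION_CATEGORY_SYSTEM = (
    "http://terminology.hl7.org/CodeSystem/condition-category"
)

RACE_CODES = [
    ("2106-3", "White"),
    ("2054-5", "Black or African American"),
    ("2028-9", "Asian"),
    ("1002-5", "American Indian or Alaska Native"),
    ("2131-1", "Other Race"),
]
ETHNICITY_CODES = [("2135-2", "Hispanic or Latino"), ("2186-5", "Not Hispanic or Latino")]
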