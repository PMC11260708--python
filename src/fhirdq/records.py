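"""FHIR R4 ingestion and the normalized resource record model.

Reads FHIR R4 resources serialized as JSON — either a Bundle (collection or
searchset) or a newline-delimited resource stream — into ``ResourceRecord``
objects, and classifies each record into the reporting subcategory used by
the volume and data-quality analyses (e.g. "Condition — Encounter diagnosis",
"Observation — Lab test").

Only the resource types exchanged for adverse-event case review are in scope
(see ``RESOURCE_TYPES``); XML serialization and StructureDefinition-level
profile validation are not.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Mapping

from ._util import maybe_date

#: Resource types received and analyzed for an AE case.
RESOURCE_TYPES = frozenset({
    "AllergyIntolerance", "Condition", "DiagnosticReport", "DocumentReference",
    "Encounter", "Immunization", "Location", "Medication", "MedicationRequest",
    "Observation", "Patient", "Practitioner", "Procedure",
})

#: Resource types that only ever arrive because another resource references
#: them (an encounter's location, a medication request's medication, ...).
AUXILIARY_TYPES = frozenset({"Location", "Medication", "Practitioner"})


class Subcategory(str, Enum):
    """Reporting strata for volume and data-quality summaries."""

    ALLERGY = "allergy"
    CONDITION_ENCOUNTER_DIAGNOSIS = "condition_encounter_diagnosis"
    CONDITION_PROBLEM_HEALTH_CONCERN = "condition_problem_health_concern"
    DIAGNOSTIC_REPORT = "diagnostic_report"
    DOCREF_CLINICAL_NOTE = "docref_clinical_note"
    DOCREF_EXTERNAL_CDA = "docref_external_cda"
    DOCREF_CORRESPONDENCE = "docref_correspondence"
    DOCREF_IMAGING_RESULT = "docref_imaging_result"
    DOCREF_HANDOFF = "docref_handoff"
    ENCOUNTER = "encounter"
    IMMUNIZATION = "immunization"
    MEDICATION_REQUEST = "medication_request"
    OBS_LAB_TEST = "obs_lab_test"
    OBS_VITAL_SIGN = "obs_vital_sign"
    OBS_LDA = "obs_lda"
    OBS_SOCIAL_HISTORY = "obs_social_history"
    OBS_OTHER = "obs_other"
    PROCEDURE_ORDER = "procedure_order"
    PROCEDURE_SURGICAL_HISTORY = "procedure_surgical_history"
    AUXILIARY = "auxiliary"
    PATIENT = "patient"


#: Subcategories excluded from per-case volume totals: auxiliary resources
#: arrive only by reference, and the single Patient resource is demographic
#: context, not a clinical event.
NON_CLINICAL_SUBCATEGORIES = frozenset({Subcategory.AUXILIARY, Subcategory.PATIENT})


@dataclass(frozen=True)
class Code:
    """A coded value: (system URI, code token, optional display text)."""

    system: str | None = None
    code: str | None = None
    display: str | None = None

    def __post_init__(self) -> None:
        if self.system is None and self.code is None:
            raise ValueError("a Code needs at least a system or a code")


@dataclass(frozen=True, order=True)
class Reference:
    """A resolved resource reference as a (target_type, target_id) pair."""

    target_type: str
    target_id: str

    def __post_init__(self) -> None:
        if not self.target_id:
            raise ValueError("reference target_id must be non-empty")


class ParseError(ValueError):
    """Raised when a source is not valid FHIR JSON; names the failing entry."""


@dataclass
class ResourceRecord:
    """One ingested FHIR resource, normalized for profiling.

    ``raw`` keeps the original JSON object so data-quality predicates can
    inspect any element; ``elements`` is a flattened path → value view of the
    same content.  ``size_bytes`` is the UTF-8 byte length of the minified
    JSON serialization (1 KB = 1024 bytes downstream).
    """

    partner_id: str
    patient_id: str
    resource_type: str
    resource_id: str
    subcategory: Subcategory
    status: str | None
    primary_code: Code | None
    event_date: _dt.date | tuple[_dt.date, _dt.date] | None
    elements: dict[str, Any]
    references: list[Reference]
    size_bytes: int
    referenced_only: bool
    raw: dict[str, Any] = field(repr=False, default_factory=dict)

    def element(self, path: str):
        """Return the value at a dotted element path, or None.

        Lists are traversed transparently: ``code.coding.system`` on a
        resource with several codings returns the first non-null hit.
        """
        return get_path(self.raw, path)


# --- element access ---------------------------------------------------------

def get_path(obj: Any, path: str):
    """Navigate a dotted path through nested dicts/lists; None if absent."""
    current: list[Any] = [obj]
    for key in path.split("."):
        nxt: list[Any] = []
        for node in current:
            if isinstance(node, list):
                candidates = node
            else:
                candidates = [node]
            for cand in candidates:
                if isinstance(cand, Mapping) and key in cand:
                    nxt.append(cand[key])
        if not nxt:
            return None
        current = nxt
    # unwrap singleton hits; flatten one list level for multi-hits
    flat: list[Any] = []
    for item in current:
        if isinstance(item, list):
            flat.extend(item)
        else:
            flat.append(item)
    if not flat:
        return None
    return flat[0] if len(flat) == 1 else flat


def _flatten(obj: Any, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            key = f"{prefix}.{k}" if prefix else k
            out.update(_flatten(v, key))
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            out.update(_flatten(v, f"{prefix}[{i}]"))
    else:
        out[prefix] = obj
    return out


# --- subcategory classification --------------------------------------------

#: Default DocumentReference stratification, keyed by LOINC document-type
#: code or by a lowercased local type/category label.  Vendor conventions,
#: not FHIR standard — override via ``classify_subcategory(docref_map=...)``.
DOCREF_STRATA: dict[str, Subcategory] = {
    # LOINC note types
    "11506-3": Subcategory.DOCREF_CLINICAL_NOTE,   # progress note
    "34117-2": Subcategory.DOCREF_CLINICAL_NOTE,   # history & physical
    "18842-5": Subcategory.DOCREF_CLINICAL_NOTE,   # discharge summary
    "11488-4": Subcategory.DOCREF_CLINICAL_NOTE,   # consult note
    "28570-0": Subcategory.DOCREF_CLINICAL_NOTE,   # procedure note
    "18748-4": Subcategory.DOCREF_IMAGING_RESULT,  # diagnostic imaging study
    "18782-3": Subcategory.DOCREF_IMAGING_RESULT,
    "24606-6": Subcategory.DOCREF_IMAGING_RESULT,
    "34133-9": Subcategory.DOCREF_EXTERNAL_CDA,    # summarization of episode (CCD)
    "64290-0": Subcategory.DOCREF_CORRESPONDENCE,
    "18761-7": Subcategory.DOCREF_HANDOFF,         # transfer summary note
    # local/vendor labels (matched on lowercased display or text)
    "external cda": Subcategory.DOCREF_EXTERNAL_CDA,
    "summary of episode note": Subcategory.DOCREF_EXTERNAL_CDA,
    "correspondence": Subcategory.DOCREF_CORRESPONDENCE,
    "letter": Subcategory.DOCREF_CORRESPONDENCE,
    "imaging result": Subcategory.DOCREF_IMAGING_RESULT,
    "diagnostic imaging study": Subcategory.DOCREF_IMAGING_RESULT,
    "handoff": Subcategory.DOCREF_HANDOFF,
    "hand-off": Subcategory.DOCREF_HANDOFF,
    "transfer summary note": Subcategory.DOCREF_HANDOFF,
}

#: Category labels identifying lines/drains/airways flowsheet observations.
LDA_CATEGORY_LABELS = frozenset({"lda", "lines-drains-airways", "lines/drains/airways"})

_OBS_CATEGORY_MAP = {
    "laboratory": Subcategory.OBS_LAB_TEST,
    "vital-signs": Subcategory.OBS_VITAL_SIGN,
    "social-history": Subcategory.OBS_SOCIAL_HISTORY,
}

_SIMPLE_TYPE_MAP = {
    "AllergyIntolerance": Subcategory.ALLERGY,
    "DiagnosticReport": Subcategory.DIAGNOSTIC_REPORT,
    "Encounter": Subcategory.ENCOUNTER,
    "Immunization": Subcategory.IMMUNIZATION,
    "MedicationRequest": Subcategory.MEDICATION_REQUEST,
    "Patient": Subcategory.PATIENT,
}


def _category_tokens(resource: Mapping) -> list[str]:
    """All category coding codes/display/text labels, lowercased."""
    tokens: list[str] = []
    raw = resource.get("category") or []
    if isinstance(raw, Mapping):  # Procedure.category is a single concept
        raw = [raw]
    for cat in raw:
        if isinstance(cat, str):
            tokens.append(cat.lower())
            continue
        for coding in cat.get("coding", []) or []:
            for k in ("code", "display"):
                if coding.get(k):
                    tokens.append(str(coding[k]).lower())
        if cat.get("text"):
            tokens.append(str(cat["text"]).lower())
    return tokens


def classify_subcategory(
    resource: Mapping,
    docref_map: Mapping[str, Subcategory] | None = None,
) -> Subcategory:
    """Assign a resource JSON object to its reporting subcategory.

    Deterministic; unmapped codings fall into the stratum's default bucket
    (obs_other for Observation, clinical-note for DocumentReference,
    problem/health-concern for Condition, order for Procedure).
    """
    rtype = resource.get("resourceType")
    if rtype in AUXILIARY_TYPES:
        return Subcategory.AUXILIARY
    if rtype in _SIMPLE_TYPE_MAP:
        return _SIMPLE_TYPE_MAP[rtype]

    tokens = _category_tokens(resource)
    if rtype == "Condition":
        if "encounter-diagnosis" in tokens:
            return Subcategory.CONDITION_ENCOUNTER_DIAGNOSIS
        return Subcategory.CONDITION_PROBLEM_HEALTH_CONCERN
    if rtype == "Observation":
        for tok in tokens:
            if tok in _OBS_CATEGORY_MAP:
                return _OBS_CATEGORY_MAP[tok]
            if tok in LDA_CATEGORY_LABELS:
                return Subcategory.OBS_LDA
        return Subcategory.OBS_OTHER
    if rtype == "Procedure":
        for tok in tokens:
            if "surgical" in tok:
                return Subcategory.PROCEDURE_SURGICAL_HISTORY
        return Subcategory.PROCEDURE_ORDER
    if rtype == "DocumentReference":
        mapping = DOCREF_STRATA if docref_map is None else docref_map
        keys: list[str] = []
        type_cc = resource.get("type") or {}
        for coding in type_cc.get("coding", []) or []:
            if coding.get("code"):
                keys.append(str(coding["code"]))
            if coding.get("display"):
                keys.append(str(coding["display"]).lower())
        if type_cc.get("text"):
            keys.append(str(type_cc["text"]).lower())
        keys.extend(tokens)
        for key in keys:
            if key in mapping:
                return mapping[key]
        return Subcategory.DOCREF_CLINICAL_NOTE
    raise ValueError(f"resource type {rtype!r} is outside the analyzed set")


# --- reference extraction ----------------------------------------------------

def extract_references(resource: Mapping) -> set[Reference]:
    """Collect distinct (target_type, target_id) pairs from all ``reference``
    elements anywhere in the resource; self-references are excluded and
    unparseable reference strings are skipped."""
    refs: set[Reference] = set()
    self_pair = (resource.get("resourceType"), resource.get("id"))

    def walk(node: Any) -> None:
        if isinstance(node, Mapping):
            ref = node.get("reference")
            if isinstance(ref, str):
                parts = ref.strip("/").split("/")
                if len(parts) == 2 and parts[0] and parts[1]:
                    if (parts[0], parts[1]) != self_pair:
                        refs.add(Reference(parts[0], parts[1]))
            for v in node.values():
                walk(v)
        elif isinstance(node, list):
            for v in node:
                walk(v)

    walk(resource)
    return refs


# --- status / primary code / event date -------------------------------------

#: Where "entered-in-error" lives: verificationStatus for Condition and
#: AllergyIntolerance, plain status elsewhere.
_VERIFICATION_STATUS_TYPES = frozenset({"Condition", "AllergyIntolerance"})


def extract_status(resource: Mapping) -> str | None:
    rtype = resource.get("resourceType")
    if rtype in _VERIFICATION_STATUS_TYPES:
        vs = resource.get("verificationStatus")
        if isinstance(vs, Mapping):
            for coding in vs.get("coding", []) or []:
                if coding.get("code"):
                    return str(coding["code"]).lower()
            if vs.get("text"):
                return str(vs["text"]).lower()
        elif isinstance(vs, str):
            return vs.lower()
        return None
    status = resource.get("status")
    return str(status).lower() if status is not None else None


_PRIMARY_CODE_PATH = {
    "AllergyIntolerance": "code",
    "Condition": "code",
    "DiagnosticReport": "code",
    "DocumentReference": "type",
    "Immunization": "vaccineCode",
    "Medication": "code",
    "MedicationRequest": "medicationCodeableConcept",
    "Observation": "code",
    "Procedure": "code",
}


def extract_primary_code(resource: Mapping) -> Code | None:
    path = _PRIMARY_CODE_PATH.get(resource.get("resourceType", ""))
    if path is None:
        return None
    cc = resource.get(path)
    if not isinstance(cc, Mapping):
        return None
    for coding in cc.get("coding", []) or []:
        if coding.get("system") or coding.get("code"):
            return Code(coding.get("system"), coding.get("code"), coding.get("display"))
    # text-only CodeableConcepts carry no machine-usable code
    return None


# Per-type date element precedence: clinically-effective time first, then
# record-keeping timestamps.
_DATE_CANDIDATES: dict[str, list[str]] = {
    "Condition": ["onsetDateTime", "onsetPeriod", "recordedDate"],
    "Observation": ["effectiveDateTime", "effectivePeriod", "issued"],
    "DiagnosticReport": ["effectiveDateTime", "effectivePeriod", "issued"],
    "DocumentReference": ["date", "context.period"],
    "Encounter": ["period"],
    "Immunization": ["occurrenceDateTime", "recorded"],
    "Procedure": ["performedDateTime", "performedPeriod"],
    "MedicationRequest": ["authoredOn"],
    "AllergyIntolerance": ["onsetDateTime", "recordedDate"],
}


def extract_event_date(resource: Mapping):
    """The record's event date — a date or a (start, end) range, or None."""
    rtype = resource.get("resourceType", "")
    for path in _DATE_CANDIDATES.get(rtype, []):
        value = get_path(resource, path)
        if value is None:
            continue
        if isinstance(value, Mapping):  # a Period
            start = maybe_date(value.get("start"))
            end = maybe_date(value.get("end"))
            if start and end:
                return (start, end)
            if start or end:
                return start or end
            continue
        d = maybe_date(value)
        if d is not None:
            return d
    return None


# --- ingestion ---------------------------------------------------------------

def serialized_size(resource: Mapping) -> int:
    """UTF-8 byte length of the minified canonical JSON serialization."""
    return len(json.dumps(resource, separators=(",", ":"), ensure_ascii=False).encode())


def record_from_resource(
    resource: Mapping,
    partner_id: str,
    patient_id: str | None = None,
    docref_map: Mapping[str, Subcategory] | None = None,
) -> ResourceRecord:
    """Normalize one parsed FHIR JSON resource object into a ResourceRecord."""
    rtype = resource.get("resourceType")
    if not rtype:
        raise ParseError("entry lacks a resourceType discriminator")
    if rtype not in RESOURCE_TYPES:
        raise ParseError(f"resource type {rtype!r} is outside the analyzed set")
    if patient_id is None:
        subj = get_path(resource, "subject.reference") or get_path(
            resource, "patient.reference"
        )
        if rtype == "Patient":
            patient_id = resource.get("id", "")
        elif isinstance(subj, str) and "/" in subj:
            patient_id = subj.strip("/").split("/")[-1]
        else:
            patient_id = ""
    return ResourceRecord(
        partner_id=partner_id,
        patient_id=patient_id,
        resource_type=rtype,
        resource_id=str(resource.get("id", "")),
        subcategory=classify_subcategory(resource, docref_map),
        status=extract_status(resource),
        primary_code=extract_primary_code(resource),
        event_date=extract_event_date(resource),
        elements=_flatten(resource),
        references=sorted(extract_references(resource)),
        size_bytes=serialized_size(resource),
        referenced_only=rtype in AUXILIARY_TYPES,
        raw=dict(resource),
    )


def read_resources(
    source: str | Path | Mapping | Iterable[Mapping],
    partner_id: str,
    patient_id: str | None = None,
    docref_map: Mapping[str, Subcategory] | None = None,
) -> list[ResourceRecord]:
    """Read FHIR R4 JSON into ResourceRecords, preserving input order.

    ``source`` may be a Bundle object, a path to a ``.json`` Bundle or
    ``.ndjson`` newline-delimited stream, a JSON string, or an iterable of
    parsed resource objects.  Auxiliary resources (Location, Medication,
    Practitioner) are marked ``referenced_only`` — they are only ever
    transmitted because another resource references them.
    """
    if not partner_id:
        raise ValueError("partner_id must be non-empty")
    resources = list(_iter_resources(source))
    records = []
    for idx, res in enumerate(resources):
        try:
            records.append(record_from_resource(res, partner_id, patient_id, docref_map))
        except ParseError as exc:
            raise ParseError(f"entry {idx}: {exc}") from exc
    return records


def _iter_resources(source) -> Iterable[Mapping]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.exists():
            text = path.read_text()
        else:
            text = str(source)
        stripped = text.strip()
        if not stripped:
            return
        if "\n" in stripped and not stripped.startswith("{"):
            raise ParseError("source is neither a JSON object nor a resource stream")
        try:
            obj = json.loads(stripped)
        except json.JSONDecodeError:
            # try newline-delimited resources
            for lineno, line in enumerate(stripped.splitlines()):
                line = line.strip()
                if not line:
                    continue
                try:
                    yield json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"entry {lineno}: malformed JSON") from exc
            return
        yield from _iter_resources(obj)
        return
    if isinstance(source, Mapping):
        if source.get("resourceType") == "Bundle":
            for idx, entry in enumerate(source.get("entry", []) or []):
                res = entry.get("resource") if isinstance(entry, Mapping) else None
                if not isinstance(res, Mapping):
                    raise ParseError(f"entry {idx}: bundle entry has no resource")
                yield res
        else:
            yield source
        return
    for item in source:
        yield item
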