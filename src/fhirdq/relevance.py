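"""Semantic-relevance filtering.

Resources whose status says the clinical action never happened — entered in
error, not done, cancelled, refuted — are often missing key data by design
and would distort volume and completeness profiles.  The filter drops them
before any counting or data-quality testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

from .records import RESOURCE_TYPES, ResourceRecord

#: Default "action never occurred" statuses per resource type.  The study's
#: exact per-type list is site configuration; this default covers FHIR R4's
#: negation statuses and is overridable via RelevancePolicy.from_config.
DEFAULT_EXCLUDED_STATUSES: dict[str, frozenset[str]] = {
    "AllergyIntolerance": frozenset({"entered-in-error", "refuted"}),
    "Condition": frozenset({"entered-in-error", "refuted"}),
    "DiagnosticReport": frozenset({"entered-in-error", "cancelled"}),
    "DocumentReference": frozenset({"entered-in-error"}),
    "Encounter": frozenset({"entered-in-error", "cancelled"}),
    "Immunization": frozenset({"entered-in-error", "not-done"}),
    "Location": frozenset(),
    "Medication": frozenset({"entered-in-error"}),
    "MedicationRequest": frozenset({"entered-in-error", "cancelled", "stopped"}),
    "Observation": frozenset({"entered-in-error", "cancelled"}),
    "Patient": frozenset(),
    "Practitioner": frozenset(),
    "Procedure": frozenset({"entered-in-error", "not-done"}),
}


@dataclass(frozen=True)
class RelevancePolicy:
    """Per-resource-type sets of excluded (lowercase) status tokens."""

    excluded_statuses: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUDED_STATUSES)
    )

    def __post_init__(self) -> None:
        normalized = {
            rtype: frozenset(s.lower() for s in statuses)
            for rtype, statuses in self.excluded_statuses.items()
        }
        for rtype in RESOURCE_TYPES:
            normalized.setdefault(rtype, frozenset())
        object.__setattr__(self, "excluded_statuses", normalized)

    @classmethod
    def from_config(cls, path_or_mapping) -> "RelevancePolicy":
        """Load a policy from a YAML/JSON file or mapping of type → statuses."""
        if isinstance(path_or_mapping, Mapping):
            data = path_or_mapping
        else:
            with open(path_or_mapping) as fh:
                data = yaml.safe_load(fh)
        return cls({k: frozenset(v) for k, v in (data or {}).items()})


def is_semantically_relevant(
    record: ResourceRecord, policy: RelevancePolicy | None = None
) -> bool:
    """True unless the record's status marks the action as never occurred.

    Records with no status are relevant.
    """
    policy = policy or RelevancePolicy()
    if record.status is None:
        return True
    excluded = policy.excluded_statuses.get(record.resource_type, frozenset())
    return record.status.lower() not in excluded


def filter_relevant(
    records: Iterable[ResourceRecord], policy: RelevancePolicy | None = None
) -> tuple[list[ResourceRecord], list[ResourceRecord]]:
    """Partition records into (kept, removed), preserving order in each.

    Idempotent on the kept list: filtering it again removes nothing.
    """
    policy = policy or RelevancePolicy()
    kept: list[ResourceRecord] = []
    removed: list[ResourceRecord] = []
    for rec in records:
        (kept if is_semantically_relevant(rec, policy) else removed).append(rec)
    return kept, removed
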