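"""Standards mapping: USCDI / U.S. Core requirement levels and vendor support.

Every tested data element is mapped to its requirement level in USCDI v1
and v3, U.S. Core IG v3.1.1 (the currently-enforced version) and v6.1.1
(the most recent balloted version), plus the level of support in the
partners' vendor FHIR API.  Coverage summaries quantify how much of the
VAERS-driven test battery today's and tomorrow's interoperability
requirements actually guarantee; the gap report lists tested elements not
currently required by U.S. Core.

Where a USCDI element definition is generic or ambiguous, partners are
assumed to meet the requirement (coverage is credited) — judgment calls on
ambiguous definitions are deliberately avoided.

The shipped default map is data (``data/standards_map.csv``), editable and
versioned with the package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources as _ilres
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from ._util import round_half_up

USCDI_LEVELS = {"required", "not_required", "na"}
USCORE_LEVELS = {"mandatory", "must_support", "optional", "not_required"}
VENDOR_LEVELS = {"required", "optional", "not_supported"}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class StandardsEntry:
    element_key: str
    resource_type: str
    element_path: str
    label: str
    priority: str      # vaers_required | vaers_optional | helpful
    category: str      # completeness | conformance | plausibility
    vaers_line: int | None
    uscdi_v1: str
    uscdi_v3: str
    uscore_3_1_1: str
    uscore_6_1_1: str
    vendor_support: str

    def __post_init__(self) -> None:
        if self.uscdi_v1 not in USCDI_LEVELS or self.uscdi_v3 not in USCDI_LEVELS:
            raise ConfigurationError(f"{self.element_key}: bad USCDI level")
        if (self.uscore_3_1_1 not in USCORE_LEVELS
                or self.uscore_6_1_1 not in USCORE_LEVELS):
            raise ConfigurationError(f"{self.element_key}: bad U.S. Core level")
        if self.vendor_support not in VENDOR_LEVELS:
            raise ConfigurationError(f"{self.element_key}: bad vendor level")


@dataclass(frozen=True)
class CoverageSummary:
    description: str
    n_total: int
    n_covered: int

    @property
    def pct(self) -> float:
        if self.n_total == 0:
            return 0.0
        return round_half_up(100.0 * self.n_covered / self.n_total, 1)


def load_standards_map(path: str | Path | None = None) -> list[StandardsEntry]:
    """Load the standards map (the shipped default when no path is given)."""
    if path is None:
        ref = _ilres.files("fhirdq").joinpath("data/standards_map.csv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    entries: list[StandardsEntry] = []
    for row in csv.DictReader(text.splitlines()):
        line = row.get("vaers_line") or None
        entries.append(StandardsEntry(
            element_key=row["element_key"],
            resource_type=row["resource_type"],
            element_path=row["element_path"],
            label=row["label"],
            priority=row["priority"],
            category=row["category"],
            vaers_line=int(line) if line else None,
            uscdi_v1=row["uscdi_v1"],
            uscdi_v3=row["uscdi_v3"],
            uscore_3_1_1=row["uscore_3_1_1"],
            uscore_6_1_1=row["uscore_6_1_1"],
            vendor_support=row["vendor_support"],
        ))
    keys = [e.element_key for e in entries]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ConfigurationError(f"duplicate element keys: {dupes}")
    return entries


# --- coverage predicates -----------------------------------------------------

def covered_by_uscore(entry: StandardsEntry) -> bool:
    """Required by the current or future U.S. Core IG (mandatory/must-support)."""
    strong = {"mandatory", "must_support"}
    return entry.uscore_3_1_1 in strong or entry.uscore_6_1_1 in strong


def vendor_supported(entry: StandardsEntry) -> bool:
    """Some level of vendor FHIR API support (required or optional)."""
    return entry.vendor_support in {"required", "optional"}


def required_completeness_conformance(entry: StandardsEntry) -> bool:
    """The VAERS-Required completeness/conformance slice of the test battery."""
    return (entry.priority == "vaers_required"
            and entry.category in {"completeness", "conformance"})


def coverage_summary(
    entries: Iterable[StandardsEntry],
    test_filter: Callable[[StandardsEntry], bool],
    coverage_predicate: Callable[[StandardsEntry], bool],
    description: str = "",
) -> CoverageSummary:
    """Fraction of filtered test-battery entries satisfying a coverage rule.

    E.g. filter = VAERS-Required completeness/conformance tests, predicate =
    covered by current-or-future U.S. Core.
    """
    selected = [e for e in entries if test_filter(e)]
    covered = [e for e in selected if coverage_predicate(e)]
    return CoverageSummary(description, len(selected), len(covered))


_PRIORITY_ORDER = {"vaers_required": 0, "vaers_optional": 1, "helpful": 2}


@dataclass(frozen=True)
class GapRow:
    element_key: str
    resource_type: str
    label: str
    priority: str
    vaers_line: int | None
    uscore_6_1_1: str
    vendor_support: str


def gap_report(entries: Iterable[StandardsEntry]) -> list[GapRow]:
    """VAERS Required/Optional data elements not currently required by
    U.S. Core (v3.1.1), with their future-IG status and vendor support.

    Sorted by priority then VAERS line; plausibility rules are not data
    elements and are excluded.
    """
    rows = [
        GapRow(e.element_key, e.resource_type, e.label, e.priority,
               e.vaers_line, e.uscore_6_1_1, e.vendor_support)
        for e in entries
        if e.priority in {"vaers_required", "vaers_optional"}
        and e.category in {"completeness", "conformance"}
        and e.uscore_3_1_1 == "not_required"
    ]
    rows.sort(key=lambda r: (_PRIORITY_ORDER[r.priority], r.vaers_line or 999,
                             r.element_key))
    return rows


def validate_references(registry, entries: Sequence[StandardsEntry]) -> None:
    """Check every registry test's standards_ref resolves to one map entry."""
    keys = {e.element_key for e in entries}
    missing = sorted(
        t.test_id for t in registry
        if t.standards_ref is not None and t.standards_ref not in keys
    )
    if missing:
        raise ConfigurationError(
            f"tests with unresolved standards references: {missing}"
        )
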