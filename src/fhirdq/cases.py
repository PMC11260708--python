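"""Case assembly: windows, date-filter policy, retrieval outcomes, cohort.

A *case* is one partner-patient adverse-event query.  Partners that supply
the immunization and AE-encounter dates get a "limited case window" — from
the immunization date through 10 days after the end of the AE encounter —
and date-bound resource types (DiagnosticReport, DocumentReference,
Observation) are filtered to that window.  Partners that cannot supply the
dates get the entire study period (2020-12-14 .. 2023-05-01).  All other
analyzed types are retained in full ("full clinical history").
"""

from __future__ import annotations

import csv
import datetime as _dt
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._util import maybe_date, round_half_up
from .records import ResourceRecord

#: Entire study period: first COVID-19 EUA administration through the
#: case-submission cut-off.
STUDY_START = _dt.date(2020, 12, 14)
STUDY_END = _dt.date(2023, 5, 1)

#: Days the limited window extends past the AE encounter end (inclusive).
WINDOW_EXTENSION_DAYS = 10

#: Types filtered by date; everything else is full clinical history.
DATE_FILTERED_TYPES = frozenset({"DiagnosticReport", "DocumentReference", "Observation"})


class WindowMode(str, Enum):
    LIMITED = "limited"
    ENTIRE_STUDY = "entire_study"


class RetrievalOutcome(str, Enum):
    SUCCESS = "success"
    MULTIPLE_MATCH = "multiple_match"
    NO_MATCH = "no_match"
    BREAK_THE_GLASS_DENIED = "break_the_glass_denied"


@dataclass(frozen=True)
class CaseWindow:
    mode: WindowMode
    start: _dt.date
    end: _dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("window start after end")

    def contains(self, event) -> bool:
        """Inclusive day-granularity test; a date-range overlaps the window."""
        if event is None:
            return False
        if isinstance(event, tuple):
            lo, hi = event
            return lo <= self.end and hi >= self.start
        return self.start <= event <= self.end


@dataclass
class Demographics:
    age_group: str | None = None
    gender: str | None = None
    race: str | None = None
    ethnicity: str | None = None
    immunization_type: str | None = None


@dataclass
class PatientCase:
    partner_id: str
    patient_id: str
    window: CaseWindow
    demographics: Demographics = field(default_factory=Demographics)
    resources: list[ResourceRecord] = field(default_factory=list)
    retrieval_outcome: RetrievalOutcome = RetrievalOutcome.SUCCESS
    query_date: _dt.date | None = None
    flagged_undated: list[ResourceRecord] = field(default_factory=list)


def compute_case_window(
    immunization_date: _dt.date | None,
    encounter_start: _dt.date | None = None,
    encounter_end: _dt.date | None = None,
) -> CaseWindow:
    """Build the case window from partner-supplied dates.

    With an immunization date: limited window from it through 10 days after
    the encounter end (the encounter start stands in when no end date was
    given).  Without one: the entire study period.
    """
    if immunization_date is None:
        return CaseWindow(WindowMode.ENTIRE_STUDY, STUDY_START, STUDY_END)
    anchor = encounter_end or encounter_start
    if anchor is None:
        # no AE encounter date at all — extend from the immunization itself
        anchor = immunization_date
    if anchor < immunization_date:
        raise ValueError("AE encounter precedes the immunization: mis-paired case")
    return CaseWindow(
        WindowMode.LIMITED,
        immunization_date,
        anchor + _dt.timedelta(days=WINDOW_EXTENSION_DAYS),
    )


def apply_window_policy(case: PatientCase) -> PatientCase:
    """Drop date-filtered records outside the case window.

    Only DiagnosticReport, DocumentReference and Observation are filtered;
    full-history types and referenced auxiliary records pass through.
    Date-filtered records with no extractable date are retained and flagged
    on ``case.flagged_undated`` rather than silently dropped.
    """
    kept: list[ResourceRecord] = []
    flagged: list[ResourceRecord] = []
    for rec in case.resources:
        if rec.resource_type not in DATE_FILTERED_TYPES:
            kept.append(rec)
            continue
        if rec.event_date is None:
            kept.append(rec)
            flagged.append(rec)
            continue
        if case.window.contains(rec.event_date):
            kept.append(rec)
    out = replace(case)
    out.resources = kept
    out.flagged_undated = flagged
    return out


def classify_retrieval(matched_count: int, security_flag: bool = False) -> RetrievalOutcome:
    """Map a patient-demographics query result to its retrieval outcome.

    More than one demographic match blocks retrieval entirely (the privacy
    rationale: any returned patient might not be the queried AE case);
    Break-the-Glass protection blocks an otherwise-unique match.
    """
    if matched_count < 0:
        raise ValueError("matched_count must be >= 0")
    if matched_count == 0:
        return RetrievalOutcome.NO_MATCH
    if matched_count > 1:
        return RetrievalOutcome.MULTIPLE_MATCH
    if security_flag:
        return RetrievalOutcome.BREAK_THE_GLASS_DENIED
    return RetrievalOutcome.SUCCESS


# --- cohort summarization ----------------------------------------------------

AGE_BANDS: Sequence[tuple[str, int, int]] = (
    ("Under 5 years", 0, 4),
    ("5-17 years", 5, 17),
    ("18-24 years", 18, 24),
    ("25-44 years", 25, 44),
    ("45-64 years", 45, 64),
    ("65 years and above", 65, 200),
)


def age_group(age_years: int | None) -> str:
    if age_years is None:
        return "Missing"
    for label, lo, hi in AGE_BANDS:
        if lo <= age_years <= hi:
            return label
    return "Missing"


@dataclass(frozen=True)
class CohortRow:
    category: str
    group: str
    count: int
    percent: float


@dataclass
class CohortSummary:
    total: int
    rows: list[CohortRow]

    def to_table(self):
        import pandas as pd

        return pd.DataFrame([r.__dict__ for r in self.rows])


_DEMO_CATEGORIES = (
    ("Age", "age_group"),
    ("Gender", "gender"),
    ("Race", "race"),
    ("Ethnicity", "ethnicity"),
    ("Immunization type", "immunization_type"),
)


def summarize_cohort(cases: Iterable[PatientCase]) -> CohortSummary:
    """Tabulate demographic counts and percentages over successful cases.

    Percentages are of the cohort total, rounded half-up to one decimal;
    missing demographics count under "Unknown".
    """
    cases = list(cases)
    for c in cases:
        if c.retrieval_outcome != RetrievalOutcome.SUCCESS:
            raise ValueError("cohort summary expects successfully retrieved cases")
    total = len(cases)
    rows: list[CohortRow] = [CohortRow("Total", "Total", total, 100.0 if total else 0.0)]
    for category, attr in _DEMO_CATEGORIES:
        counts: Counter[str] = Counter()
        for c in cases:
            value = getattr(c.demographics, attr) or "Unknown"
            counts[value] += 1
        for group, n in counts.most_common():
            pct = round_half_up(100.0 * n / total, 1) if total else 0.0
            rows.append(CohortRow(category, group, n, pct))
    return CohortSummary(total=total, rows=rows)


# --- case manifest I/O -------------------------------------------------------

MANIFEST_COLUMNS = [
    "partner_id", "patient_id", "immunization_date", "encounter_start",
    "encounter_end", "matched_count", "security_flag", "query_date",
    "age", "gender", "race", "ethnicity", "immunization_type",
]


def read_manifest(path: str | Path) -> list[dict]:
    """Read the per-case manifest (one row per queried case, CSV)."""
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def case_from_manifest_row(row: Mapping[str, str]) -> PatientCase:
    """Build an (empty) PatientCase from one manifest row."""
    imm = maybe_date(row.get("immunization_date") or None)
    enc_start = maybe_date(row.get("encounter_start") or None)
    enc_end = maybe_date(row.get("encounter_end") or None)
    window = compute_case_window(imm, enc_start, enc_end)
    matched = int(row.get("matched_count") or 1)
    flag = str(row.get("security_flag", "")).lower() in {"1", "true", "yes"}
    age = row.get("age")
    demo = Demographics(
        age_group=age_group(int(age)) if age not in (None, "") else "Missing",
        gender=row.get("gender") or None,
        race=row.get("race") or None,
        ethnicity=row.get("ethnicity") or None,
        immunization_type=row.get("immunization_type") or None,
    )
    return PatientCase(
        partner_id=row["partner_id"],
        patient_id=row["patient_id"],
        window=window,
        demographics=demo,
        retrieval_outcome=classify_retrieval(matched, flag),
        query_date=maybe_date(row.get("query_date") or None),
    )
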