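"""Shared helpers: half-up rounding and FHIR date parsing."""

from __future__ import annotations

import datetime as _dt
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round ``value`` to ``ndigits`` decimals with ties going away from zero.

    Python's built-in ``round`` uses banker's rounding; report tables here
    follow the half-up convention (0.05 -> 0.1 at one decimal).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def parse_fhir_date(value: str) -> _dt.date:
    """Parse a FHIR date/dateTime/instant string to a calendar date.

    Accepts ``YYYY``, ``YYYY-MM``, ``YYYY-MM-DD`` and full dateTimes with an
    optional timezone; time of day is dropped (day granularity throughout).
    Partial dates resolve to the first day of the period.
    """
    if not isinstance(value, str) or not value:
        raise ValueError(f"not a FHIR date: {value!r}")
    datepart = value.split("T")[0]
    parts = datepart.split("-")
    try:
        year = int(parts[0])
        month = int(parts[1]) if len(parts) > 1 else 1
        day = int(parts[2]) if len(parts) > 2 else 1
        return _dt.date(year, month, day)
    except (ValueError, IndexError) as exc:
        raise ValueError(f"not a FHIR date: {value!r}") from exc


def maybe_date(value) -> _dt.date | None:
    """Best-effort date parse; returns None for missing/unparseable input."""
    if value is None:
        return None
    if isinstance(value, _dt.date):
        return value
    try:
        return parse_fhir_date(value)
    except ValueError:
        return None
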