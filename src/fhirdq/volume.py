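"""Volume characterization: per-case counts, partner aggregation, sizes.

The volume profile answers "how much clinical data arrives per AE case?".
Counts include only semantically-relevant resources and exclude resources
that arrived purely by reference (a practitioner referenced by an encounter
appears across many resources and would be double-counted).  Partner-level
statistics are computed on each partner's mean count per case, then the
min / max / median / average are taken across partners.  Resource sizes are
estimated from a random sample of up to 100 relevant resources per
subcategory (KB = 1024 bytes, two decimals).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import round_half_up
from .cases import PatientCase, WindowMode
from .records import NON_CLINICAL_SUBCATEGORIES, ResourceRecord, Subcategory
from .relevance import RelevancePolicy, is_semantically_relevant

#: Pseudo-subcategory for the per-partner sum over clinical subcategories.
TOTAL_ROW = "total_resources"


def count_case_resources(
    case: PatientCase, policy: RelevancePolicy | None = None
) -> dict[Subcategory, int]:
    """Count a case's semantically-relevant, directly-queried resources.

    Referenced-only records and the auxiliary/patient subcategories are
    excluded; every clinical subcategory appears in the result (zero counts
    included).
    """
    policy = policy or RelevancePolicy()
    counts = {
        sub: 0 for sub in Subcategory if sub not in NON_CLINICAL_SUBCATEGORIES
    }
    for rec in case.resources:
        if rec.referenced_only or rec.subcategory in NON_CLINICAL_SUBCATEGORIES:
            continue
        if not is_semantically_relevant(rec, policy):
            continue
        counts[rec.subcategory] += 1
    return counts


@dataclass(frozen=True)
class VolumeRow:
    """Across-partner statistics of the per-partner mean count per case."""

    window_mode: WindowMode
    subcategory: str
    partner_means: tuple[float, ...]
    median: float
    average: float
    min: float
    max: float


@dataclass
class VolumeSummary:
    window_mode: WindowMode
    rows: dict[str, VolumeRow]

    def to_table(self):
        import pandas as pd

        recs = []
        for key, row in self.rows.items():
            recs.append({
                "window_mode": self.window_mode.value,
                "subcategory": key,
                "median": round_half_up(row.median, 1),
                "average": round_half_up(row.average, 1),
                "min": round_half_up(row.min, 1),
                "max": round_half_up(row.max, 1),
            })
        return pd.DataFrame(recs)


def aggregate_partner_volume(
    per_case_counts: Mapping[str, Sequence[Mapping[Subcategory, int]]],
    window_mode: WindowMode = WindowMode.LIMITED,
) -> VolumeSummary:
    """Aggregate per-case counts to across-partner volume statistics.

    ``per_case_counts`` maps partner_id → one count mapping per case.  For
    each subcategory the partner mean count per case is computed first; the
    median / average / min / max are then taken over those partner means
    (even-n median: mean of the two central values).  A ``total_resources``
    row sums each partner's subcategory means before aggregating.
    """
    partner_means: dict[str, dict[str, float]] = defaultdict(dict)  # sub -> partner -> mean
    for partner, case_counts in per_case_counts.items():
        if len(case_counts) == 0:
            import warnings

            warnings.warn(f"partner {partner!r} has no cases; excluded", stacklevel=2)
            continue
        subs = set()
        for cc in case_counts:
            subs.update(cc)
        total = 0.0
        for sub in subs:
            mean = float(np.mean([cc.get(sub, 0) for cc in case_counts]))
            key = sub.value if isinstance(sub, Subcategory) else str(sub)
            partner_means[key][partner] = mean
            total += mean
        partner_means[TOTAL_ROW][partner] = total

    rows: dict[str, VolumeRow] = {}
    for key, by_partner in partner_means.items():
        means = tuple(by_partner[p] for p in sorted(by_partner))
        arr = np.asarray(means, dtype=float)
        rows[key] = VolumeRow(
            window_mode=window_mode,
            subcategory=key,
            partner_means=means,
            median=float(np.median(arr)),
            average=float(arr.mean()),
            min=float(arr.min()),
            max=float(arr.max()),
        )
    return VolumeSummary(window_mode=window_mode, rows=rows)


def volume_from_cases(
    cases: Iterable[PatientCase],
    policy: RelevancePolicy | None = None,
    window_mode: WindowMode | None = None,
) -> VolumeSummary:
    """Convenience: count, group by partner, and aggregate in one call."""
    grouped: dict[str, list[dict[Subcategory, int]]] = defaultdict(list)
    mode = window_mode
    for case in cases:
        if window_mode is not None and case.window.mode != window_mode:
            continue
        grouped[case.partner_id].append(count_case_resources(case, policy))
        mode = mode or case.window.mode
    return aggregate_partner_volume(grouped, mode or WindowMode.LIMITED)


@dataclass(frozen=True)
class SizeEstimate:
    subcategory: str
    sample_size: int
    mean_kb: float
    seed: int


def estimate_resource_size(
    records: Sequence[ResourceRecord],
    subcategory: Subcategory | str,
    n: int = 100,
    seed: int = 0,
    policy: RelevancePolicy | None = None,
) -> SizeEstimate | None:
    """Mean serialized size (KB, 2 dp) of a random sample of resources.

    Samples uniformly without replacement, capped at the number of available
    relevant records in the subcategory; deterministic for a fixed seed.
    Returns None when no record is available (a "-" table cell).
    """
    policy = policy or RelevancePolicy()
    key = subcategory.value if isinstance(subcategory, Subcategory) else subcategory
    pool = [
        r for r in records
        if (r.subcategory.value == key) and is_semantically_relevant(r, policy)
    ]
    if not pool:
        return None
    rng = np.random.default_rng(seed)
    k = min(n, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False)
    mean_kb = float(np.mean([pool[i].size_bytes for i in idx])) / 1024.0
    return SizeEstimate(key, k, round_half_up(mean_kb, 2), seed)


def estimate_case_size(avg_count: float, est_size_kb: float) -> float:
    """Estimated total KB per case: count x per-resource size, 2 dp half-up."""
    if avg_count < 0 or est_size_kb < 0:
        raise ValueError("inputs must be non-negative")
    return round_half_up(avg_count * est_size_kb, 2)
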