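"""Synthetic multi-partner FHIR adverse-event case corpus generator.

Emulates the shape of a multi-partner HIE pilot: a configurable number of
partner organizations each queried for ~30 post-vaccination AE cases, with
per-case retrieval failures (multiple/no demographic match, Break-the-Glass
denial), per-subcategory resource counts drawn from an over-dispersed
(negative binomial) model, element-level missingness, locally-defined code
systems, semantically-irrelevant statuses, and per-case query timings.

Every random decision is recorded in a ``GroundTruth`` sidecar, so every
pipeline statistic has a known expectation (``expected_statistics``) and
planted defects can be recounted exactly.

The generated corpus is plain FHIR R4 JSON plus the same manifest/timing
CSV formats the pipeline ingests; no clinical realism is attempted beyond
what the profiling stages exercise.
"""

from __future__ import annotations

import base64
import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import vocab
from .cases import (
    STUDY_END, STUDY_START, Demographics, PatientCase, RetrievalOutcome,
    WindowMode, age_group, apply_window_policy, classify_retrieval,
    compute_case_window,
)
from .records import Subcategory, read_resources
from .timing import QueryTiming

SUB = Subcategory

#: Default per-subcategory mean relevant-resource counts per case, by window
#: mode — the partner-average volumes observed in the emulated study.
DEFAULT_COUNT_MEANS: dict[WindowMode, dict[Subcategory, float]] = {
    WindowMode.LIMITED: {
        SUB.ALLERGY: 2.7, SUB.CONDITION_ENCOUNTER_DIAGNOSIS: 205.9,
        SUB.CONDITION_PROBLEM_HEALTH_CONCERN: 14.6, SUB.DIAGNOSTIC_REPORT: 27.4,
        SUB.DOCREF_CLINICAL_NOTE: 67.7, SUB.DOCREF_EXTERNAL_CDA: 60.1,
        SUB.DOCREF_CORRESPONDENCE: 20.2, SUB.DOCREF_IMAGING_RESULT: 21.5,
        SUB.DOCREF_HANDOFF: 0.3, SUB.ENCOUNTER: 206.1, SUB.IMMUNIZATION: 14.8,
        SUB.MEDICATION_REQUEST: 131.3, SUB.OBS_LAB_TEST: 130.1,
        SUB.OBS_VITAL_SIGN: 49.4, SUB.OBS_LDA: 8.3, SUB.OBS_SOCIAL_HISTORY: 8.6,
        SUB.OBS_OTHER: 0.0, SUB.PROCEDURE_ORDER: 9.9,
        SUB.PROCEDURE_SURGICAL_HISTORY: 5.1,
    },
    WindowMode.ENTIRE_STUDY: {
        SUB.ALLERGY: 4.1, SUB.CONDITION_ENCOUNTER_DIAGNOSIS: 181.3,
        SUB.CONDITION_PROBLEM_HEALTH_CONCERN: 15.2, SUB.DIAGNOSTIC_REPORT: 50.0,
        SUB.DOCREF_CLINICAL_NOTE: 204.9, SUB.DOCREF_EXTERNAL_CDA: 42.5,
        SUB.DOCREF_CORRESPONDENCE: 22.2, SUB.DOCREF_IMAGING_RESULT: 33.0,
        SUB.DOCREF_HANDOFF: 0.2, SUB.ENCOUNTER: 170.5, SUB.IMMUNIZATION: 9.3,
        SUB.MEDICATION_REQUEST: 206.3, SUB.OBS_LAB_TEST: 348.4,
        SUB.OBS_VITAL_SIGN: 178.4, SUB.OBS_LDA: 23.3,
        SUB.OBS_SOCIAL_HISTORY: 13.8, SUB.OBS_OTHER: 0.0,
        SUB.PROCEDURE_ORDER: 5.2, SUB.PROCEDURE_SURGICAL_HISTORY: 7.2,
    },
}

#: Default probability that a given element is populated.  Keys are
#: (resource_type, element_path); anything unlisted defaults to 1.0.
DEFAULT_COMPLETENESS: dict[tuple[str, str], float] = {
    ("Immunization", "lotNumber"): 0.85,
    ("Immunization", "manufacturer"): 0.85,
    ("Immunization", "site"): 0.90,
    ("Immunization", "route"): 0.90,
    ("Immunization", "protocolApplied.doseNumberPositiveInt"): 0.50,
    ("Immunization", "reaction"): 0.10,
    ("Condition", "onsetDateTime"): 0.70,
    ("Condition", "abatementDateTime"): 0.30,
    ("Condition", "asserter"): 0.20,
    ("Patient", "address.country"): 0.80,
    ("Patient", "extension.us-core-race"): 0.90,
    ("Patient", "extension.us-core-ethnicity"): 0.90,
    ("Patient", "extension.us-veteran-status"): 0.05,
    ("Practitioner", "telecom"): 0.60,
    ("Location", "telecom"): 0.70,
    ("Location", "type"): 0.70,
    ("AllergyIntolerance", "onsetDateTime"): 0.50,
    ("Immunization", "doseQuantity"): 0.40,
}

#: Per-element local-code-system rates overriding the global rate.  Site and
#: route are bound only to *example* value sets upstream and arrive as
#: locally-defined codes essentially always.
DEFAULT_LOCAL_RATES: dict[tuple[str, str], float] = {
    ("Immunization", "site"): 1.0,
    ("Immunization", "route"): 1.0,
}

#: Demographic group probabilities emulating the pilot cohort composition.
DEFAULT_DEMOGRAPHICS_MIX: dict[str, dict[str, float]] = {
    "age_group": {
        "Under 5 years": 16, "5-17 years": 16, "18-24 years": 16,
        "25-44 years": 72, "45-64 years": 95, "65 years and above": 68,
    },
    "gender": {"Male": 72, "Female": 210, "Unknown": 1},
    "race": {
        "White": 167, "Black or African American": 37,
        "Asian/Pacific Islander": 10, "American Indian or Alaska Native": 3,
        "Other": 38, "Unknown": 28,
    },
    "ethnicity": {"Hispanic": 29, "Non-Hispanic": 223, "Unknown": 31},
    "immunization_type": {
        "COVID-19": 249, "Pneumococcal conjugate PCV 13": 9, "Tdap": 8,
        "MMRV": 4, "Unspecified": 3, "Meningococcal MCV4O": 1, "Influenza": 6,
    },
}

_AGE_RANGES = {
    "Under 5 years": (0, 4), "5-17 years": (5, 17), "18-24 years": (18, 24),
    "25-44 years": (25, 44), "45-64 years": (45, 64),
    "65 years and above": (65, 95),
}

_WORDS = (
    "patient presented with fever chills myalgia following vaccination "
    "reviewed history vitals stable administered observation plan follow up "
    "no acute distress symptoms resolved discharged home tolerated well"
).split()


@dataclass
class GeneratorConfig:
    """Study-condition parameters for corpus generation.

    Defaults emulate the pilot: 11 partners, 30 queried cases each, six
    partners able to supply case dates (limited window) and five not
    (entire study period), 18.7% combined demographic-match failures and
    2.2% Break-the-Glass denials, study-scale per-subcategory volumes.
    """

    seed: int = 0
    n_partners: int = 11
    cases_per_partner: int = 30
    n_limited_partners: int = 6
    count_means: Mapping[WindowMode, Mapping[Subcategory, float]] | None = None
    count_dispersion: float = 5.0
    element_completeness: dict[tuple[str, str], float] = field(default_factory=dict)
    local_code_rate: float = 0.05
    local_code_rates: dict[tuple[str, str], float] = field(default_factory=dict)
    irrelevant_status_rate: float = 0.02
    multiple_match_rate: float = 0.12
    no_match_rate: float = 0.067
    btg_rate: float = 0.022
    demographics_mix: Mapping[str, Mapping[str, float]] | None = None
    timing_median_s: Mapping[WindowMode, float] = field(
        default_factory=lambda: {WindowMode.LIMITED: 210.0,
                                 WindowMode.ENTIRE_STUDY: 584.0})
    timing_sigma: float = 0.9
    note_bytes: int = 2048

    def __post_init__(self) -> None:
        for name in ("local_code_rate", "irrelevant_status_rate",
                     "multiple_match_rate", "no_match_rate", "btg_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for p in self.element_completeness.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("element_completeness values must be probabilities")
        if self.multiple_match_rate + self.no_match_rate + self.btg_rate > 1.0:
            raise ValueError("retrieval failure rates sum past 1")
        if self.n_limited_partners > self.n_partners:
            raise ValueError("n_limited_partners exceeds n_partners")

    def completeness(self, rtype: str, path: str) -> float:
        key = (rtype, path)
        if key in self.element_completeness:
            return self.element_completeness[key]
        return DEFAULT_COMPLETENESS.get(key, 1.0)

    def local_rate(self, rtype: str, path: str) -> float:
        key = (rtype, path)
        if key in self.local_code_rates:
            return self.local_code_rates[key]
        return DEFAULT_LOCAL_RATES.get(key, self.local_code_rate)

    def means(self, mode: WindowMode) -> dict[Subcategory, float]:
        src = self.count_means or DEFAULT_COUNT_MEANS
        table = src.get(mode) or {}
        return {SUB(k) if not isinstance(k, SUB) else k: float(v)
                for k, v in table.items()}

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """A reduced-volume configuration for fast exercises: same rates and
        structure, ~2 resources per subcategory per case."""
        means = {
            mode: {sub: min(v, 2.0) for sub, v in table.items()}
            for mode, table in DEFAULT_COUNT_MEANS.items()
        }
        defaults = dict(n_partners=4, cases_per_partner=8, n_limited_partners=2,
                        count_means=means)
        defaults.update(overrides)
        return cls(seed=seed, **defaults)


@dataclass
class GroundTruth:
    """Exact record of what the generator planted, per partner."""

    window_mode: dict[str, str] = field(default_factory=dict)
    n_queried: dict[str, int] = field(default_factory=dict)
    n_success: dict[str, int] = field(default_factory=dict)
    outcome_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    #: partner -> "rtype.path" -> [n_present, n_total]
    element_counts: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    #: partner -> "rtype.path" -> [n_standard_system, n_total]
    code_system_counts: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    #: partner -> subcategory -> total relevant resources over cases
    relevant_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    irrelevant_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class Corpus:
    """A generated corpus: one bundle per successful case plus sidecars."""

    config: GeneratorConfig
    bundles: dict[str, dict]                 # case_id -> Bundle JSON object
    manifest: list[dict]                     # one row per queried case
    timings: list[QueryTiming]
    ground_truth: GroundTruth

    def to_cases(self, apply_window: bool = True) -> list[PatientCase]:
        """Ingest the corpus through the normal reading path."""
        cases = []
        for row in self.manifest:
            outcome = classify_retrieval(
                int(row["matched_count"]),
                str(row["security_flag"]).lower() in {"1", "true"},
            )
            window = compute_case_window(
                _d(row["immunization_date"]), _d(row["encounter_start"]),
                _d(row["encounter_end"]),
            )
            demo = Demographics(
                age_group=age_group(int(row["age"])) if row["age"] != "" else "Missing",
                gender=row["gender"], race=row["race"], ethnicity=row["ethnicity"],
                immunization_type=row["immunization_type"],
            )
            case = PatientCase(
                partner_id=row["partner_id"], patient_id=row["patient_id"],
                window=window, demographics=demo, retrieval_outcome=outcome,
                query_date=_d(row["query_date"]),
            )
            if outcome is RetrievalOutcome.SUCCESS:
                bundle = self.bundles[row["case_id"]]
                case.resources = read_resources(
                    bundle, row["partner_id"], row["patient_id"]
                )
                if apply_window:
                    case = apply_window_policy(case)
            cases.append(case)
        return cases

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "bundles").mkdir(parents=True, exist_ok=True)
        for case_id, bundle in self.bundles.items():
            (out / "bundles" / f"{case_id}.json").write_text(
                json.dumps(bundle, indent=1))
        import csv as _csv

        cols = ["case_id", "partner_id", "patient_id", "immunization_date",
                "encounter_start", "encounter_end", "matched_count",
                "security_flag", "query_date", "age", "gender", "race",
                "ethnicity", "immunization_type"]
        with open(out / "manifest.csv", "w", newline="") as fh:
            w = _csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            w.writerows(self.manifest)
        from .timing import write_timings

        write_timings(self.timings, out / "timings.csv")
        (out / "ground_truth.json").write_text(self.ground_truth.to_json())


def _d(value: str):
    return _dt.date.fromisoformat(value) if value else None


# --- generation --------------------------------------------------------------

class _Gen:
    def __init__(self, config: GeneratorConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.gt = GroundTruth()

    # -- bookkeeping

    def _tally(self, table: dict, partner: str, key: str, hit: bool) -> None:
        cell = table.setdefault(partner, {}).setdefault(key, [0, 0])
        cell[1] += 1
        if hit:
            cell[0] += 1

    def present(self, partner: str, rtype: str, path: str) -> bool:
        p = self.cfg.completeness(rtype, path)
        hit = bool(self.rng.random() < p)
        self._tally(self.gt.element_counts, partner, f"{rtype}.{path}", hit)
        return hit

    def standard_system(self, partner: str, rtype: str, path: str) -> bool:
        rate = self.cfg.local_rate(rtype, path)
        local = bool(self.rng.random() < rate)
        self._tally(self.gt.code_system_counts, partner, f"{rtype}.{path}", not local)
        return not local

    def coding(self, partner: str, rtype: str, path: str, system: str,
               codes: list[str], display: str | None = None) -> dict:
        if self.standard_system(partner, rtype, path):
            code = str(self.rng.choice(codes))
            return {"system": system, "code": code,
                    **({"display": display} if display else {})}
        return {"system": f"{vocab.LOCAL_SYSTEM_PREFIX}/{partner}",
                "code": f"LOC{int(self.rng.integers(1, 9999))}",
                "display": display or "local code"}

    def ncount(self, mean: float) -> int:
        if mean <= 0:
            return 0
        k = self.cfg.count_dispersion
        return int(self.rng.negative_binomial(k, k / (k + mean)))

    def date_in(self, start: _dt.date, end: _dt.date) -> _dt.date:
        span = max((end - start).days, 0)
        return start + _dt.timedelta(days=int(self.rng.integers(0, span + 1)))

    def prose(self, n_bytes: int) -> str:
        words = []
        size = 0
        while size < n_bytes:
            w = str(self.rng.choice(_WORDS))
            words.append(w)
            size += len(w) + 1
        return " ".join(words)


def generate_corpus(config: GeneratorConfig | None = None) -> Corpus:
    """Generate a corpus; byte-identical for identical configs."""
    cfg = config or GeneratorConfig()
    g = _Gen(cfg)
    rng = g.rng
    bundles: dict[str, dict] = {}
    manifest: list[dict] = []
    timings: list[QueryTiming] = []
    mix = cfg.demographics_mix or DEFAULT_DEMOGRAPHICS_MIX

    for pi in range(cfg.n_partners):
        partner = f"partner{pi + 1:02d}"
        mode = (WindowMode.LIMITED if pi < cfg.n_limited_partners
                else WindowMode.ENTIRE_STUDY)
        g.gt.window_mode[partner] = mode.value
        g.gt.n_queried[partner] = cfg.cases_per_partner
        g.gt.n_success[partner] = 0
        g.gt.outcome_counts[partner] = {o.value: 0 for o in RetrievalOutcome}
        g.gt.relevant_counts[partner] = {}
        g.gt.irrelevant_counts[partner] = 0
        means = cfg.means(mode)

        for ci in range(cfg.cases_per_partner):
            case_id = f"{partner}-c{ci + 1:03d}"
            patient_id = f"{partner}-p{ci + 1:03d}"
            demo = {cat: _draw_group(rng, groups) for cat, groups in mix.items()}
            lo, hi = _AGE_RANGES.get(demo.get("age_group", ""), (18, 90))
            age = int(rng.integers(lo, hi + 1))

            # retrieval outcome
            u = rng.random()
            if u < cfg.multiple_match_rate:
                outcome, matched, flag = RetrievalOutcome.MULTIPLE_MATCH, 2, False
            elif u < cfg.multiple_match_rate + cfg.no_match_rate:
                outcome, matched, flag = RetrievalOutcome.NO_MATCH, 0, False
            elif u < cfg.multiple_match_rate + cfg.no_match_rate + cfg.btg_rate:
                outcome, matched, flag = RetrievalOutcome.BREAK_THE_GLASS_DENIED, 1, True
            else:
                outcome, matched, flag = RetrievalOutcome.SUCCESS, 1, False
            g.gt.outcome_counts[partner][outcome.value] += 1

            imm_date = g.date_in(STUDY_START, STUDY_END - _dt.timedelta(days=40))
            enc_start = imm_date + _dt.timedelta(days=int(rng.integers(0, 15)))
            enc_end = enc_start + _dt.timedelta(days=int(rng.integers(0, 4)))
            query_date = STUDY_END + _dt.timedelta(days=int(rng.integers(30, 120)))
            window = compute_case_window(
                imm_date if mode is WindowMode.LIMITED else None,
                enc_start, enc_end)

            manifest.append({
                "case_id": case_id, "partner_id": partner,
                "patient_id": patient_id,
                "immunization_date": imm_date.isoformat() if mode is WindowMode.LIMITED else "",
                "encounter_start": enc_start.isoformat() if mode is WindowMode.LIMITED else "",
                "encounter_end": enc_end.isoformat() if mode is WindowMode.LIMITED else "",
                "matched_count": matched, "security_flag": int(flag),
                "query_date": query_date.isoformat(), "age": age,
                "gender": demo["gender"], "race": demo["race"],
                "ethnicity": demo["ethnicity"],
                "immunization_type": demo["immunization_type"],
            })

            if outcome is not RetrievalOutcome.SUCCESS:
                continue
            g.gt.n_success[partner] += 1

            birth = imm_date - _dt.timedelta(days=age * 365 + int(rng.integers(0, 365)))
            resources = _case_resources(
                g, partner, patient_id, means, window.start, window.end,
                imm_date, enc_start, enc_end, birth, demo, mode)
            bundles[case_id] = {
                "resourceType": "Bundle", "type": "collection", "id": case_id,
                "entry": [{"resource": r} for r in resources],
            }

            # timing
            median = float(cfg.timing_median_s[mode])
            dur = max(5, int(round(median * float(np.exp(
                cfg.timing_sigma * rng.standard_normal())))))
            started = _dt.datetime.combine(query_date, _dt.time(9, 0))
            timings.append(QueryTiming(
                case_id, mode, started, started + _dt.timedelta(seconds=dur)))

    return Corpus(cfg, bundles, manifest, timings, g.gt)


def _draw_group(rng, groups: Mapping[str, float]) -> str:
    names = list(groups)
    weights = np.asarray([float(groups[n]) for n in names], dtype=float)
    weights = weights / weights.sum()
    return names[int(rng.choice(len(names), p=weights))]


def _case_resources(
    g: _Gen, partner: str, patient_id: str, means, win_start, win_end,
    imm_date, enc_start, enc_end, birth, demo, mode,
) -> list[dict]:
    cfg = g.cfg
    rng = g.rng
    resources: list[dict] = [
        _patient(g, partner, patient_id, birth, demo)]
    aux: list[dict] = []
    seq: dict[str, int] = {}

    def rid(prefix: str) -> str:
        seq[prefix] = seq.get(prefix, 0) + 1
        return f"{patient_id}-{prefix}{seq[prefix]}"

    # shared auxiliary resources, referenced (not directly queried)
    loc_id, pract_id = rid("loc"), rid("pract")
    aux.append(_location(g, partner, loc_id))
    aux.append(_practitioner(g, partner, pract_id))

    def count_relevant(sub: Subcategory, n: int) -> None:
        g.gt.relevant_counts[partner][sub.value] = (
            g.gt.relevant_counts[partner].get(sub.value, 0) + n)

    # draw all counts up front so cross-references (AE condition -> its
    # encounter) are only emitted when the target will exist
    ordered = sorted(means.items(), key=lambda kv: kv[0].value)
    drawn = {}
    for sub, mean in ordered:
        n_rel = g.ncount(mean)
        n_irr = int(rng.poisson(mean * cfg.irrelevant_status_rate))
        drawn[sub] = (n_rel, n_irr)
        count_relevant(sub, n_rel)
        g.gt.irrelevant_counts[partner] += n_irr
    has_encounter = drawn.get(SUB.ENCOUNTER, (0, 0))[0] >= 1
    has_condition = drawn.get(SUB.CONDITION_ENCOUNTER_DIAGNOSIS, (0, 0))[0] >= 1
    ev_floor = max(win_start, birth)

    for sub, _mean in ordered:
        n_rel, n_irr = drawn[sub]
        for j in range(n_rel + n_irr):
            irrelevant = j >= n_rel
            ev = g.date_in(ev_floor, win_end)
            first = j == 0
            res = _build_resource(
                g, partner, patient_id, sub, rid, ev, loc_id, pract_id,
                imm_date if first else ev, enc_start, enc_end, demo,
                irrelevant=irrelevant, is_index=first,
                has_encounter=has_encounter, has_condition=has_condition)
            if res is not None:
                resources.append(res)
                if sub is SUB.MEDICATION_REQUEST and "medicationReference" in res:
                    med_id = res["medicationReference"]["reference"].split("/")[1]
                    aux.append(_medication(g, partner, med_id))
    resources.extend(aux)
    return resources


# --- resource builders -------------------------------------------------------

def _patient(g: _Gen, partner: str, pid: str, birth, demo) -> dict:
    cfg = g.cfg
    res: dict[str, Any] = {"resourceType": "Patient", "id": pid}
    if g.present(partner, "Patient", "name"):
        res["name"] = [{"family": f"Fam{pid[-3:]}", "given": ["Synth"]}]
    if g.present(partner, "Patient", "birthDate"):
        res["birthDate"] = birth.isoformat()
    if g.present(partner, "Patient", "gender"):
        res["gender"] = {"Male": "male", "Female": "female"}.get(
            demo.get("gender", ""), "unknown")
    if g.present(partner, "Patient", "address"):
        addr: dict[str, Any] = {"city": "Springfield", "state": "VA",
                                "postalCode": "22150"}
        if g.present(partner, "Patient", "address.country"):
            addr["country"] = "US"
        res["address"] = [addr]
    ext = []
    if g.present(partner, "Patient", "extension.us-core-race"):
        code, disp = vocab.RACE_CODES[int(g.rng.integers(0, len(vocab.RACE_CODES)))]
        ext.append({
            "url": "http://hl7.org/fhir/us/core/StructureDefinition/us-core-race",
            "extension": [{"url": "ombCategory", "valueCoding": {
                "system": "urn:oid:2.16.840.1.113883.6.238",
                "code": code, "display": disp}}],
        })
    if g.present(partner, "Patient", "extension.us-core-ethnicity"):
        code, disp = vocab.ETHNICITY_CODES[int(g.rng.integers(0, 2))]
        ext.append({
            "url": "http://hl7.org/fhir/us/core/StructureDefinition/us-core-ethnicity",
            "extension": [{"url": "ombCategory", "valueCoding": {
                "system": "urn:oid:2.16.840.1.113883.6.238",
                "code": code, "display": disp}}],
        })
    if g.present(partner, "Patient", "extension.us-veteran-status"):
        ext.append({"url": "http://hl7.org/fhir/us/military-service/"
                           "StructureDefinition/us-veteran-status",
                    "valueBoolean": bool(g.rng.random() < 0.1)})
    if ext:
        res["extension"] = ext
    if g.rng.random() < 0.02:  # rare deceased patients exercise death-date tests
        res["deceasedDateTime"] = (birth + _dt.timedelta(
            days=int(g.rng.integers(400, 20000)))).isoformat()
    else:
        res["deceasedBoolean"] = False
    return res


def _location(g: _Gen, partner: str, rid: str) -> dict:
    res: dict[str, Any] = {"resourceType": "Location", "id": rid,
                           "name": f"{partner} clinic", "status": "active"}
    if g.present(partner, "Location", "telecom"):
        res["telecom"] = [{"system": "phone", "value": "555-0100"}]
    if g.present(partner, "Location", "type"):
        res["type"] = [{"coding": [{
            "system": "http://terminology.hl7.org/CodeSystem/v3-RoleCode",
            "code": "OF", "display": "Outpatient facility"}]}]
    return res


def _practitioner(g: _Gen, partner: str, rid: str) -> dict:
    res: dict[str, Any] = {"resourceType": "Practitioner", "id": rid,
                           "name": [{"family": "Provider", "given": ["Pat"]}],
                           "active": True}
    if g.present(partner, "Practitioner", "telecom"):
        res["telecom"] = [{"system": "phone", "value": "555-0101"}]
    return res


def _medication(g: _Gen, partner: str, rid: str) -> dict:
    return {"resourceType": "Medication", "id": rid, "status": "active",
            "code": {"coding": [g.coding(partner, "Medication", "code",
                                         vocab.RXNORM, vocab.RXNORM_CODES)]}}


_IRRELEVANT_STATUS = {
    "AllergyIntolerance": "entered-in-error", "Condition": "entered-in-error",
    "DiagnosticReport": "entered-in-error", "DocumentReference": "entered-in-error",
    "Encounter": "cancelled", "Immunization": "not-done",
    "MedicationRequest": "cancelled", "Observation": "entered-in-error",
    "Procedure": "not-done",
}

_DOCREF_TYPE = {
    SUB.DOCREF_CLINICAL_NOTE: ("11506-3", "Progress note", vocab.LOINC),
    SUB.DOCREF_EXTERNAL_CDA: ("34133-9", "Summary of episode note", vocab.LOINC),
    SUB.DOCREF_IMAGING_RESULT: ("18748-4", "Diagnostic imaging study", vocab.LOINC),
    SUB.DOCREF_CORRESPONDENCE: ("64290-0", "Correspondence", vocab.LOINC),
    SUB.DOCREF_HANDOFF: ("18761-7", "Transfer summary note", vocab.LOINC),
}


def _build_resource(
    g: _Gen, partner: str, patient_id: str, sub: Subcategory, rid, ev_date,
    loc_id, pract_id, imm_date, enc_start, enc_end, demo,
    irrelevant: bool, is_index: bool, has_encounter: bool = False,
    has_condition: bool = False,
) -> dict | None:
    subject = {"reference": f"Patient/{patient_id}"}
    rng = g.rng

    if sub is SUB.IMMUNIZATION:
        res: dict[str, Any] = {
            "resourceType": "Immunization", "id": rid("imm"),
            "status": _IRRELEVANT_STATUS["Immunization"] if irrelevant else "completed",
            "patient": subject,
            "vaccineCode": {"coding": [g.coding(
                partner, "Immunization", "vaccineCode", vocab.CVX,
                vocab.CVX_CODES, demo.get("immunization_type"))]},
        }
        if g.present(partner, "Immunization", "occurrenceDateTime"):
            res["occurrenceDateTime"] = (imm_date if is_index else ev_date).isoformat()
        if g.present(partner, "Immunization", "lotNumber"):
            res["lotNumber"] = f"LOT{int(rng.integers(1000, 9999))}"
        if g.present(partner, "Immunization", "manufacturer"):
            res["manufacturer"] = {"display": str(rng.choice(
                ["Pfizer-BioNTech", "Moderna", "Novavax", "GSK"]))}
        if g.present(partner, "Immunization", "site"):
            res["site"] = {"coding": [g.coding(
                partner, "Immunization", "site", vocab.SITE_SYSTEM,
                sorted(vocab.SITE_VALUE_SET), "Left deltoid")]}
        if g.present(partner, "Immunization", "route"):
            res["route"] = {"coding": [g.coding(
                partner, "Immunization", "route", vocab.ROUTE_SYSTEM,
                sorted(vocab.ROUTE_VALUE_SET), "Intramuscular")]}
        if g.present(partner, "Immunization", "protocolApplied.doseNumberPositiveInt"):
            res["protocolApplied"] = [{"doseNumberPositiveInt": int(rng.integers(1, 4))}]
        if g.present(partner, "Immunization", "doseQuantity"):
            res["doseQuantity"] = {"value": 0.5, "unit": "mL", "system": vocab.UCUM}
        if g.present(partner, "Immunization", "reaction"):
            res["reaction"] = [{"date": ev_date.isoformat(),
                                "reported": True}]
        return res

    if sub in (SUB.CONDITION_ENCOUNTER_DIAGNOSIS, SUB.CONDITION_PROBLEM_HEALTH_CONCERN):
        is_dx = sub is SUB.CONDITION_ENCOUNTER_DIAGNOSIS
        res = {
            "resourceType": "Condition", "id": rid("cond"), "subject": subject,
            "category": [{"coding": [{
                "system": vocab.CONDITION_CATEGORY_SYSTEM,
                "code": "encounter-diagnosis" if is_dx else "problem-list-item"}]}],
            "verificationStatus": {"coding": [{
                "system": "http://terminology.hl7.org/CodeSystem/condition-ver-status",
                "code": "entered-in-error" if irrelevant else "confirmed"}]},
            "code": {"coding": [g.coding(partner, "Condition", "code",
                                         vocab.SNOMED, vocab.SNOMED_CONDITION_CODES)]},
            "recordedDate": ev_date.isoformat(),
        }
        if g.present(partner, "Condition", "onsetDateTime"):
            res["onsetDateTime"] = ev_date.isoformat()
            if g.present(partner, "Condition", "abatementDateTime"):
                res["abatementDateTime"] = (
                    ev_date + _dt.timedelta(days=int(rng.integers(0, 30)))
                ).isoformat()
        if g.present(partner, "Condition", "asserter"):
            res["asserter"] = {"reference": f"Practitioner/{pract_id}"}
        if is_dx and has_encounter:
            res["encounter"] = {"reference": f"Encounter/{patient_id}-enc1"}
        return res

    if sub is SUB.ENCOUNTER:
        start = enc_start if is_index else ev_date
        end = enc_end if is_index else ev_date
        res = {
            "resourceType": "Encounter", "id": rid("enc"),
            "status": _IRRELEVANT_STATUS["Encounter"] if irrelevant else "finished",
            "subject": subject,
            "class": {"system": "http://terminology.hl7.org/CodeSystem/v3-ActCode",
                      "code": "AMB", "display": "ambulatory"},
            "period": {"start": start.isoformat(), "end": end.isoformat()},
            "location": [{"location": {"reference": f"Location/{loc_id}"}}],
            "participant": [{"individual": {
                "reference": f"Practitioner/{pract_id}"}}],
        }
        if g.present(partner, "Encounter", "diagnosis"):
            res["diagnosis"] = [{"condition": {
                "reference": f"Condition/{patient_id}-cond1"}}]
        return res

    if sub in (SUB.OBS_LAB_TEST, SUB.OBS_VITAL_SIGN, SUB.OBS_LDA,
               SUB.OBS_SOCIAL_HISTORY, SUB.OBS_OTHER):
        cat_code, codes = {
            SUB.OBS_LAB_TEST: ("laboratory", vocab.LOINC_LAB_CODES),
            SUB.OBS_VITAL_SIGN: ("vital-signs", vocab.LOINC_VITAL_CODES),
            SUB.OBS_SOCIAL_HISTORY: ("social-history", ["72166-2"]),
            SUB.OBS_LDA: ("LDA", ["8339-4"]),
            SUB.OBS_OTHER: ("survey", ["58258-5"]),
        }[sub]
        res = {
            "resourceType": "Observation", "id": rid("obs"),
            "status": _IRRELEVANT_STATUS["Observation"] if irrelevant else "final",
            "subject": subject,
            "category": [{"coding": [{
                "system": vocab.OBSERVATION_CATEGORY_SYSTEM, "code": cat_code}]}],
            "code": {"coding": [g.coding(partner, "Observation", "code",
                                         vocab.LOINC, codes)]},
            "effectiveDateTime": ev_date.isoformat(),
        }
        if g.present(partner, "Observation", "value"):
            res["valueQuantity"] = {"value": round(float(rng.uniform(1, 200)), 1),
                                    "unit": "1", "system": vocab.UCUM}
        return res

    if sub is SUB.DIAGNOSTIC_REPORT:
        return {
            "resourceType": "DiagnosticReport", "id": rid("dxr"),
            "status": _IRRELEVANT_STATUS["DiagnosticReport"] if irrelevant else "final",
            "subject": subject,
            "code": {"coding": [g.coding(partner, "DiagnosticReport", "code",
                                         vocab.LOINC, vocab.LOINC_LAB_CODES)]},
            "effectiveDateTime": ev_date.isoformat(),
        }

    if sub in _DOCREF_TYPE:
        code, display, system = _DOCREF_TYPE[sub]
        if code is not None and g.standard_system(partner, "DocumentReference", "type"):
            type_cc = {"coding": [{"system": system, "code": code,
                                   "display": display}], "text": display}
        else:
            type_cc = {"coding": [{
                "system": f"{vocab.LOCAL_SYSTEM_PREFIX}/{partner}",
                "code": f"DOC{int(rng.integers(1, 999))}", "display": display}],
                "text": display}
        res = {
            "resourceType": "DocumentReference", "id": rid("doc"),
            "status": "entered-in-error" if irrelevant else "current",
            "subject": subject, "type": type_cc,
        }
        if g.present(partner, "DocumentReference", "date"):
            res["date"] = ev_date.isoformat()
        if g.present(partner, "DocumentReference", "content"):
            text = g.prose(g.cfg.note_bytes)
            res["content"] = [{"attachment": {
                "contentType": "text/plain",
                "data": base64.b64encode(text.encode()).decode()}}]
        else:
            res["content"] = [{"attachment": {"contentType": "text/plain"}}]
        res["context"] = {"period": {"start": ev_date.isoformat(),
                                     "end": ev_date.isoformat()}}
        return res

    if sub is SUB.MEDICATION_REQUEST:
        res = {
            "resourceType": "MedicationRequest", "id": rid("mr"),
            "status": _IRRELEVANT_STATUS["MedicationRequest"] if irrelevant else "active",
            "intent": "order", "subject": subject,
            "authoredOn": ev_date.isoformat(),
        }
        if rng.random() < 0.3:
            res["medicationReference"] = {
                "reference": f"Medication/{rid('med')}"}
        else:
            res["medicationCodeableConcept"] = {"coding": [g.coding(
                partner, "MedicationRequest", "medicationCodeableConcept",
                vocab.RXNORM, vocab.RXNORM_CODES)]}
        return res

    if sub in (SUB.PROCEDURE_ORDER, SUB.PROCEDURE_SURGICAL_HISTORY):
        surgical = sub is SUB.PROCEDURE_SURGICAL_HISTORY
        res = {
            "resourceType": "Procedure", "id": rid("proc"),
            "status": _IRRELEVANT_STATUS["Procedure"] if irrelevant else "completed",
            "subject": subject,
            "category": {"coding": [{"system": vocab.SNOMED,
                                     "code": "387713003" if surgical else "103693007",
                                     "display": ("Surgical procedure" if surgical
                                                 else "Diagnostic procedure")}]},
            "code": {"coding": [g.coding(partner, "Procedure", "code",
                                         vocab.SNOMED,
                                         vocab.SNOMED_CONDITION_CODES)]},
            "performedDateTime": ev_date.isoformat(),
        }
        return res

    if sub is SUB.ALLERGY:
        res = {
            "resourceType": "AllergyIntolerance", "id": rid("alg"),
            "patient": subject,
            "verificationStatus": {"coding": [{
                "system": "http://terminology.hl7.org/CodeSystem/"
                          "allergyintolerance-verification",
                "code": "entered-in-error" if irrelevant else "confirmed"}]},
            "code": {"coding": [g.coding(partner, "AllergyIntolerance", "code",
                                         vocab.RXNORM, vocab.RXNORM_CODES)]},
            "recordedDate": ev_date.isoformat(),
        }
        if g.present(partner, "AllergyIntolerance", "onsetDateTime"):
            res["onsetDateTime"] = ev_date.isoformat()
        return res

    return None


# --- analytic expectations ---------------------------------------------------

def expected_statistics(config: GeneratorConfig | None = None) -> dict[str, Any]:
    """Analytic expectations implied by a generator configuration.

    Completeness-test pass rates are 100 x the element-presence probability;
    code-system conformance rates are 100 x (1 - local-code rate); the case
    retrieval success fraction is 1 minus the three failure rates; partner
    mean counts per subcategory equal the configured means.
    """
    cfg = config or GeneratorConfig()
    success = 1.0 - (cfg.multiple_match_rate + cfg.no_match_rate + cfg.btg_rate)
    completeness = {
        f"{rtype}.{path}": 100.0 * cfg.completeness(rtype, path)
        for (rtype, path) in set(DEFAULT_COMPLETENESS) | set(cfg.element_completeness)
    }
    conformance = {
        key: 100.0 * (1.0 - cfg.local_rate(*key.split(".", 1)))
        for key in ("Condition.code", "Observation.code", "Immunization.vaccineCode",
                    "MedicationRequest.medicationCodeableConcept")
    }
    return {
        "success_fraction": success,
        "expected_completeness_pct": completeness,
        "expected_conformance_pct": conformance,
        "expected_partner_mean_counts": {
            mode.value: {s.value: m for s, m in cfg.means(mode).items()}
            for mode in WindowMode
        },
    }
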