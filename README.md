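# fhirdq

Volume, timeliness and data-quality profiling for FHIR R4 post-vaccination
adverse-event (AE) case bundles exchanged over a health-information-exchange
(HIE) network.

## The problem

Passive vaccine-safety surveillance (VAERS) reports are frequently incomplete,
and following up a single report can take days to weeks of manual exchange
between a public-health agency and the reporting provider. With FHIR R4 APIs
now federally mandated for certified EHRs, an agency can instead *query* a
provider network for the full clinical record of a suspected AE case. The
practical questions are then: how much data arrives per case, how fast, and —
critically — are the data elements a safety reviewer needs actually present,
coded interoperably, and believable?

`fhirdq` is a pipeline for answering those questions over multi-partner
corpora of FHIR AE-case bundles. It is aimed at health-informatics teams
evaluating FHIR-based surveillance pipelines and at anyone who needs a
reproducible, testable implementation of EHR data-quality profiling in the
Kahn framework.

## What it computes

- **Ingestion** (`fhirdq.records`) — FHIR R4 JSON Bundles or NDJSON streams
  → normalized records, classified into reporting subcategories
  (Condition — encounter diagnosis, Observation — lab test, five
  DocumentReference strata, …).
- **Semantic relevance** (`fhirdq.relevance`) — drops resources whose status
  (`entered-in-error`, `not-done`, …) says the clinical action never
  occurred.
- **Case assembly** (`fhirdq.cases`) — per-case date windows (a *limited
  case window* runs from the immunization date to 10 days after the AE
  encounter ends; otherwise the entire study period 2020‑12‑14 … 2023‑05‑01),
  retrieval-outcome classification (success / multiple match / no match /
  Break-the-Glass denied), and cohort demographics.
- **Volume** (`fhirdq.volume`) — per-case counts of relevant,
  directly-queried resources by subcategory; per-partner means; across-partner
  min/max/median/average; sampled per-resource size estimates
  (≤100 resources/subcategory, KB = 1024 bytes) and estimated case sizes.
- **Data quality** (`fhirdq.dq`) — a categorized test registry
  (completeness × conformance × plausibility, prioritized by VAERS form
  requirement level), evaluated per resource and reported as the percentage
  of applicable resources passing, per partner, with across-partner averages
  (the strip-plot data contract).
- **Standards mapping** (`fhirdq.standards`) — each tested element mapped to
  USCDI v1/v3, U.S. Core IG v3.1.1/v6.1.1 and vendor FHIR-API support levels,
  with coverage summaries and a gap report of elements not currently required
  by U.S. Core.
- **Timing** (`fhirdq.timing`) — end-to-end query-response durations
  summarized per window mode (min/max/range/median/IQR, `H:MM:SS`).
- **Synthetic data** (`fhirdq.synth`) — a seeded multi-partner corpus
  generator with known ground truth (planted element missingness, local-code
  rates, irrelevant statuses, retrieval-failure rates), so every pipeline
  statistic can be verified against its analytic expectation.

## Worked example

Generate a reduced synthetic corpus (4 partners × 8 queried cases, ~2
resources per subcategory per case) and run the whole pipeline:

```bash
fhirdq all --seed 1 --out demo_reports
```

This prints an overview (abridged):

```
{
 "cohort_total": 29,
 "n_cases_queried": 32,
 "n_cases_successful": 29,
 "n_dq_tests": 60,
 "n_gap_elements": 18,
 "retrieval_success_pct": 90.6,
 "uscore_coverage_pct": 74.2,
 "vendor_support_pct": 87.1,
 ...
}
```

Of 32 queried cases, 29 were retrievable (the rest drew demographic-match or
Break-the-Glass failures at the configured rates). The shipped standards map
shows 74.2% (23/31) of VAERS-Required completeness/conformance elements
covered by current-or-future U.S. Core requirements and 87.1% (27/31) with
some vendor API support; 18 tested elements are not currently required by
U.S. Core (`gap_report.csv`). `demo_reports/` also contains the volume
tables per window mode, e.g.:

```
window_mode,subcategory,median,average,min,max,est_size_per_resource_kb,est_avg_total_kb
limited,diagnostic_report,2.1,2.1,1.7,2.4,0.23,0.48
limited,docref_imaging_result,1.9,1.9,1.9,2.0,3.08,5.85
```

(each row: across-partner statistics of the partner-mean count per case,
plus the sampled per-resource size and the estimated per-case KB), the
long-format DQ results `dq_results.csv` (test × partner × pass percentage)
with `dq_stripplot.csv` across-partner averages, and the timing summary:

```
case_type,minimum,maximum,range,median
limited,0:00:35,0:18:26,0:17:51,0:02:04
entire_study,0:02:51,0:32:23,0:29:32,0:11:07
```

Entire-study-period cases take longer to retrieve than limited-window cases,
as the synthetic timing model intends. Reruns with the same seed are
byte-identical.

The same reports can be produced from an on-disk corpus
(`fhirdq generate --out corpus && fhirdq report corpus --out reports`), and
each stage is available as a library function.

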