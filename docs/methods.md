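# Methods

This note documents the models, conventions and design decisions behind
`fhirdq`, in the spirit of a statistical package's methods documentation.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and data model

The pipeline profiles corpora of FHIR R4 resources retrieved for
post-vaccination adverse-event (AE) cases, grouped by partner organization
and patient case. Thirteen resource types are in scope: AllergyIntolerance,
Condition, DiagnosticReport, DocumentReference, Encounter, Immunization,
Location, Medication, MedicationRequest, Observation, Patient, Practitioner
and Procedure. Location, Medication and Practitioner are *auxiliary*: they
are only ever transmitted because another resource references them, and are
flagged `referenced_only` on ingest.

Resources are read directly from FHIR JSON (Bundle of type
collection/searchset, or newline-delimited streams) with the standard
library JSON parser; FHIR JSON is ordinary JSON and the package performs no
StructureDefinition-level profile validation (out of scope), so no FHIR
object model is required. XML serialization and FHIR versions other than R4
are not supported.

### Subcategory classification

Volume and DQ reporting use clinical strata finer than resource type:

- Condition splits on category coding into *encounter diagnosis* versus
  *problem/health concern* (default bucket: problem/health concern, since
  problem-list membership is the safer assumption for uncategorized
  conditions).
- Observation splits on category into lab test, vital sign, social history,
  LDA (lines/drains/airways — an EHR flowsheet stratum, identified by a
  configurable label list) and a residual *other* bucket.
- DocumentReference splits into clinical notes, external CDA,
  correspondence, imaging results and handoff documents. These strata are
  vendor conventions, not FHIR standard, so the mapping is a configurable
  table keyed by LOINC document-type code or lowercased local label
  (`fhirdq.records.DOCREF_STRATA`); unmapped types default to the clinical
  note stratum.
- Procedure splits into orders versus surgical history on its category
  coding (any label containing "surgical").
- The Patient resource gets its own `patient` stratum: it is demographic
  context rather than a clinical event, and like the auxiliary stratum it
  is excluded from per-case volume totals.

### Element precedence conventions

- Event date per type: the clinically-effective time first, then
  record-keeping timestamps (Condition: onset → recordedDate; Observation
  and DiagnosticReport: effective → issued; DocumentReference: date →
  context period; Immunization: occurrence → recorded; Procedure:
  performed; MedicationRequest: authoredOn; Encounter: period). Period
  values yield a (start, end) date range.
- Status: `verificationStatus` for Condition and AllergyIntolerance (where
  `entered-in-error` lives), `status` for all other types.
- Serialized size: UTF-8 byte length of the minified JSON form; 1 KB =
  1024 bytes. A fixed convention so size estimates are reproducible across
  formatters.

## Semantic relevance

Resources whose status indicates the clinical action never occurred are
excluded from volume counts and DQ denominators — they are missing key data
*by design* and would read as spurious quality defects. The default
exclusion list (`fhirdq.relevance.DEFAULT_EXCLUDED_STATUSES`) covers FHIR
R4's negation statuses per type (`entered-in-error`, `not-done`,
`cancelled`, `refuted`, `stopped` for MedicationRequest) and is fully
overridable via a YAML/JSON policy file, since the exact list is site
configuration.

## Case windows and date filtering

A case whose partner supplied the immunization and AE-encounter dates gets
a **limited case window**: from the immunization date through 10 days after
the AE encounter's end (the encounter start stands in when no end was
given). Both endpoints are inclusive, at day granularity. Cases without an
immunization date get the **entire study period**, 2020-12-14 through
2023-05-01 (first COVID-19 EUA administration through the case cut-off).

Only DiagnosticReport, DocumentReference and Observation are date-filtered;
all other types are retained as full clinical history, and referenced
auxiliary resources are always retained. Date-filtered records with no
extractable date are kept and flagged rather than dropped — dropping them
would silently bias the completeness tests that specifically target missing
dates. Period-valued records are in-window if the period overlaps the
window (conservative inclusion).

Retrieval outcomes follow the HIE's patient-demographics query semantics:
zero matches → `no_match`; more than one match → `multiple_match` (the
exchange refuses to return any of them); a unique match behind an extra
access-control layer → `break_the_glass_denied`; otherwise success.

## Volume statistics

Per case, the pipeline counts semantically-relevant, directly-queried
resources per subcategory (auxiliary/patient strata and referenced-only
records excluded — referenced resources recur across resources and patients
and would inflate volume through double counting). Partner-level statistics
are two-stage: each partner's mean count per case first, then the
min/max/median/average across partner means. The median of an even number
of partners is the mean of the two central values. A *total resources* row
sums each partner's subcategory means before aggregating.

Per-resource sizes are estimated from a uniform random sample without
replacement of up to 100 relevant resources per subcategory (deterministic
given a seed); the estimated per-case size is
`round_half_up(mean count × per-resource KB, 2)`. Counts are reported to
1 decimal and sizes to 2, both half-up. Transport-level measurement
(compression, HTTP overhead) is out of scope.

## Data-quality engine

Tests follow the Kahn harmonized framework — completeness, conformance,
plausibility — crossed with a VAERS-form priority: *VAERS Required*
(fields the form marks essential), *VAERS Optional* (all other form
fields), *Helpful* (elements clinicians flag as useful for AE review).

A test is a pair of predicates over a normalized record plus its case
context (the case's Patient resource, query date, resource roster):
*applicability* selects the denominator, *evaluate* returns
pass/fail/not-applicable. The reported statistic is the percentage of
applicable **resources** passing, per partner, to 1 decimal half-up;
patient-level tests treat each Patient resource as one applicable record.
Zero applicable resources yields NA (a missing strip-plot point), and
across-partner averages are taken over non-NA partners only.

Conventions chosen where the semantics were genuinely open:

- Conformance passes only on a coding whose system URI is in the allowed
  set with a non-empty code that is not the invalid placeholder `"0"`;
  value-set tests (immunization site/route) additionally require set
  membership. A missing element fails conformance — the resource is not
  interoperably coded. Allowed systems are configuration, seeded with
  CVX / SNOMED CT / ICD-10-CM / LOINC / RxNorm URIs; the site/route value
  sets ship as editable lists because upstream requirements leave them
  example-bound.
- Boundary dates pass plausibility: an event on the birth date is
  clinically valid (birth-day care), onset equal to abatement is valid.
  Missing operands yield not-applicable, never failure.
- The RxNorm conformance test follows `medicationReference` to the case's
  Medication resource when the request has no inline code.

The built-in registry (60 concrete tests) implements the named test
families: immunization detail completeness (lot number, manufacturer, site,
route, dose number, reaction and reaction date), condition and encounter
dates and references, patient demographics and death data (death date
scoped to deceased patients), clinical-note retrieval and dating,
practitioner/location contact and site type, code-system conformance, and
temporal/uniqueness plausibility. It is extensible by constructing further
`DQTest` objects. The full assessment battery of the emulated study is site
configuration and not public; its declared 3×3 accounting
(`STUDY_REGISTRY_MANIFEST`, 330 tests) ships as data so the registry
accounting identities (row and column sums equal the grand total) can be
checked and reported alongside the concrete registry's own accounting.

## Standards map

Each tested element carries its requirement level in USCDI v1 and v3,
U.S. Core IG v3.1.1 (currently enforced) and v6.1.1 (most recent balloted),
and the vendor FHIR-API support level (`data/standards_map.csv`, editable
and versioned). "Covered" means mandatory or must-support in the current or
future U.S. Core IG; "vendor supported" means required or optional support.
Where a USCDI definition is generic or ambiguous, partners are *assumed* to
meet it (coverage credited) — the map deliberately avoids judgment calls on
ambiguous definitions. The gap report lists VAERS Required/Optional
completeness/conformance elements not currently required by U.S. Core;
plausibility rules are excluded because they are not data elements.

## Timing

Durations are whole seconds between case-query start and completion
timestamps, end-to-end only — the measured interval spans many hops by
design and no per-hop attribution is attempted. Statistics per window mode:
min, max, range, median (even n: mean of the central pair), average, and
IQR by linear interpolation between order statistics (quantile type 7).
Formatting is `H:MM:SS` with unpadded hours. Observed medians from any real
deployment are infrastructure-dependent and are not targets of this
package.

## Synthetic-data generator

The generator emulates the study conditions of a multi-partner HIE pilot:

- **Structure**: 11 partners × 30 queried cases by default; 6 partners can
  supply case dates (limited window), 5 cannot (entire study period).
- **Retrieval failures**: 12% multiple-match + 6.7% no-match (18.7%
  combined demographic-match failures; the split between the two is not
  separately published and was fixed once, multiple-match dominant) and
  2.2% Break-the-Glass, giving an expected 79.1% success fraction.
- **Counts**: per-subcategory negative binomial (over-dispersed counts are
  typical of per-patient EHR event volumes) with dispersion 5.0 and means
  set to the study-scale partner averages per window mode; the configured
  mean is the mean of *relevant* resources, with irrelevant-status records
  added on top at the configured rate so expectations stay exact.
- **Defects**: each element present with its configured probability
  (defaults mid-to-high for the historically gappy immunization and date
  elements, 1.0 elsewhere); codes drawn from packaged sample vocabularies
  or from a partner-local system at the configured local-code rate
  (default 5%, but 100% for immunization site and route, which arrive
  locally coded essentially always); statuses negated at the irrelevant
  rate.
- **Timing**: log-normal durations (σ = 0.9) with medians 210 s
  (limited) and 584 s (entire study).
- **Demographics**: drawn from the pilot cohort's published composition;
  patient birth dates are consistent with the drawn age band at the
  immunization date, and event dates are clamped to on/after birth so a
  defect-free configuration passes every plausibility test.
- **Ground truth**: every presence/code-system/outcome draw is tallied per
  partner, so planted defects can be recounted exactly from the raw
  bundles, and `expected_statistics` gives the analytic expectation of
  every pipeline statistic.

Clinical-note text is seeded placeholder prose of configurable byte length
(default ~2 KB) purely to exercise size estimation; no clinical realism,
disease trajectories or identifiable data are attempted, and the sample
vocabularies are tiny non-exhaustive slices. Consequently, passing tests
demonstrate correct *measurement* — recovery of known planted rates, exact
arithmetic, deterministic reports — not that real partner data would show
any particular quality level.

### Problem sizes used in tests and the acceptance script

The test suite and acceptance script run the generator at reduced volumes —
`GeneratorConfig.small()` caps subcategory means at ~2 per case, and the
defect-recovery check uses 5 partners × 30 cases with study-scale
immunization counts (≈1,900 applicable immunizations) — sizes chosen so
recovery intervals are tight while suites stay fast. Study-scale defaults
remain available via the plain `GeneratorConfig()`.

## Numerical conventions

Half-up decimal rounding throughout reporting (1 dp for counts and
percentages, 2 dp for KB); NA propagation instead of division by zero;
window comparisons at day granularity; deterministic iteration order
everywhere (sorted partners, fixed subcategory order), so identical seeds
give byte-identical corpora and reports.

## Known limitations

- The built-in registry reconstructs test semantics from element
  definitions; a deployment's exact FHIR search predicates may differ.
- The default relevance policy and DocumentReference strata mapping are
  reasonable defaults, not the (unpublished) site configuration of any
  particular deployment; both are overridable.
- The standards map is a snapshot: USCDI/U.S. Core ballots move, and the
  map is data to be re-edited, not a live tracker.
- Percentages are computed per resource; no patient- or partner-weighted
  alternatives are offered.
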