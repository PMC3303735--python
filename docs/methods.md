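# Methods

This note documents the models, conventions and design choices behind
`oncostar`, and what its synthetic test harness does and does not show.

## The warehouse model

The warehouse is a star schema: a single observation-fact table and four
dimensions (patients, visits, providers, concepts). A fact is one coded
statement about a patient at a visit; its unique key is
`(patient_id, visit_id, concept_code, obs_date, instance_num)` and
re-inserting a key replaces the stored row (last-wins), which is what makes
every load re-runnable. Dates are ISO-8601 at day precision throughout —
nothing in the pipeline needs intraday resolution, and day precision keeps
the delimited-text round-trip exact.

Concept hierarchy is encoded in the path string itself:
backslash-delimited, with leading and trailing delimiter
(`\SNOMED\Neoplasm and hamartoma\Neoplasm malignant\`). The trailing
delimiter is load-bearing: it makes a plain prefix test segment-aligned
(`\A\B\` can never match `\A\BC\`), so hierarchy expansion is a string
operation with no tree walk. `level` equals the number of segments, and
every non-root concept must have its parent path present — both are
enforced by `integrity_check`, which reports violations as data rather
than raising, so a corrupted store can be triaged in one pass.

Storage is deliberately a plain in-memory container with a TSV
export/import; a database server would add nothing at this scale and would
make the test matrix platform-dependent.

## The concept ontology

The morphology branch is built from a packaged nested term tree (~40
breast-lesion terms under a "neoplasm and hamartoma" root). Codes follow
the familiar axis-letter + five digits surface form but are lexicon
entries owned by this package — they are deliberately *not* asserted
against any terminology release, since shipping real terminology content
is a licensing and versioning problem this package does not have to solve.
An optional reader accepts an RDF/XML subclass hierarchy (via rdflib) for
users who have an OWL extract of a real terminology.

Concept *names*, not term ids, form path segments: the path is the
human-browsable tree, and the term id is kept as the concept code.
Duplicate sibling names are rejected outright rather than silently
suffixed — a silent rename would make two differently-shaped trees produce
identical paths depending on input order.

## Report extraction

Reports produced by structured data entry are predictable enough that a
configuration-driven pattern pipeline extracts their coded content
exactly. Two stages:

1. **Sectionizer** — configured header patterns (English and Italian
   aliases) split the report; text before the first header is the
   preamble (report id, date, specimen number). A report with no
   diagnosis header is an error, not a silent empty result.
2. **Field extractors** — run *only* on the diagnosis section. This is the
   pipeline's central correctness property: prose in the anamnesis (e.g.
   an outside lab's Ki-67 value) must never contaminate the coded output,
   and the synthetic generator plants exactly such decoys to prove it.

Conventions where multiple readings are defensible: the first mention of a
field wins and later conflicting mentions are logged; hormone receptors
reported qualitatively ("positive"/"negative") are carried as status
strings beside the percent fields rather than mapped to sentinel numbers,
and become text-valued facts at load; percent fields outside [0, 100]
raise rather than clamp. TNM is parsed against closed vocabularies
(T: X,0,is,1,1a–1c,2,3,4,4a–4d; N: X,0,1,1a,2,2a,3; M: X,0,1) with an
optional c/p/yp prefix; the serialized form round-trips through the
parser.

The XML output (one document per report) validates against the packaged
schema on read. One historic spelling of the progesterone-receptor element
("…recoptors") is tolerated on read through an alias map; writing always
uses the corrected spelling.

## Anonymization

The barcode payload is `FSM-BB-` + ten characters of Crockford base-32
(no I/L/O/U — unambiguous on a frozen-vial label) + a mod-37 check
character, hyphen-grouped 3-3-3-2. The grouping is a privacy design, not
cosmetics: no run of four consecutive alphanumerics exists in any payload,
so no length-≥4 fragment of an (all-alphabetic) donor name can ever occur
in one, making the leak-scan property structural rather than
probabilistic. Synthetic pathology-unit patient ids use only letters
excluded from the barcode alphabet for the same reason.

The payload↔donor lookup is a separate store with its own loader, saved in
its own directory and never co-exported with warehouse or biobank tables;
resolution requires an explicit authorization flag. Process-level
isolation is documented intent, not something a library can enforce.

## ETL

Sync (pathology unit → biobank) is incremental on an `updated_at`
watermark with a processed-id guard, filters on research consent, mints a
fresh barcode per admitted specimen, and quarantines malformed rows
without stopping. Scheduling (the real system syncs many times a day and
merges weekly) is modelled as explicit calls with timestamps — a daemon
would only obscure the state machine under test.

The load maps: HIS visits → visit dimension; sex and vital status → facts
at the patient's first visit; each report → one fact per morphology code,
three facts per TNM mention (one per T/N/M component — the combined code
would defeat hierarchical querying; the c/p/yp prefix is retained in the
XML but has no warehouse concept), numeric biomarker facts with `%` units
where applicable; each sample → a material fact carrying the payload as
text value, plus project and sample-type meta facts (creation date and
description remain sample-table annotations — they are descriptive, not
cohort-selection criteria). Samples attach to the visit whose start date
equals the collection date, falling back to the first visit. Unknown codes
are logged and skipped; reports or samples with no HIS patient are counted
as orphans; instance numbers are assigned by a per-load deterministic
counter, so the whole load is key-idempotent.

## Queries

Panel semantics: OR within a panel across the hierarchy-expanded concept
items, AND across panels, per-panel inversion complementing against the
patient dimension. Value and date constraints bind to the same fact that
matched the concept (a patient with Ki-67 30% in 2005 and 10% in 2009
matches "Ki-67 ≥ 20 in 2005", not by mixing facts). A value constraint
meeting a non-numeric matched fact is a type error rather than a silent
non-match. Deduplication is patient-level. The engine is verified against
an independent brute-force fact-table scan over randomized definitions.

## Survival

The product-limit estimator is computed from first principles (it is one
of the package's deliverables, so it is not delegated): distinct event
times, nᵢ = subjects with time ≥ tᵢ, so observations censored exactly at
an event time count as at risk through it; S multiplies (1 − dᵢ/nᵢ);
the median is the first time S ≤ 0.5, undefined if never reached.
Greenwood standard errors are available behind a flag. Warehouse-derived
records use overall survival with the index date at the patient's first
morphology-coded fact and administrative censoring at a caller-supplied
date. The test suite cross-checks against an independently developed
product-limit implementation to 1e-12.

## The synthetic cohort

The generator emulates the source ecosystem this kind of platform
integrates, at the published shape of the deployed system: the default
biobanked fraction is 393/6713 ≈ 0.0585 (the reported fraction of
patients with at least one banked sample) and dates span 2001–2011.
Per-patient defaults chosen once as field-plausible: 1–6 visits on
distinct days; 1–2 reports (85% histological); 1–3 morphology codes per
report; TNM present for 85% of histological reports; ER/PR present 90%
with a point mass at 0 and a 10% qualitative-only variant; Ki-67 roughly
uniform on 1–90%; HER-2 scores uniform over {0..3}; grade present 85%;
sex 98.5% female; 25% of patients draw a death time 60–2500 days after
first diagnosis (beyond-window deaths become administrative censoring);
~3% of non-biobanked patients contribute a non-consented specimen that the
sync must skip. All randomness flows from one seeded `random.Random`; the
same seed reproduces every artifact byte for byte.

Noise levels: `none` renders canonical templates (the regime in which
extraction is validated at 100%); `light` perturbs header wording, case
and spacing but never coded tokens; `heavy` may additionally drop whole
field lines — extraction may then return *absent*, but never a wrong
value for an unperturbed field. At every level the anamnesis may carry a
decoy Ki-67 mention that must not be extracted.

Donor identity fields (names, PU ids) exist solely to exercise the
anonymization checks: they are written to the pathology-unit source table
and nowhere else. The name pools were chosen so that no case-normalized
4-gram of any name occurs in any string class that reaches warehouse or
biobank exports (concept names, enums, column headers, provider labels);
a guard test enforces this, so the leak scan measures the pipeline, not
lucky vocabulary.

What passing tests on this harness show: structural and semantic
correctness of every stage against known ground truth, conservation
end-to-end, idempotence, and privacy properties of the export surface.
What they do not show: robustness to genuinely free-form clinical prose
(real reports have typos, negations and layout drift far beyond the
templated noise here), realistic breast-cancer epidemiology (the cohort
is a test harness, not a disease model), or terminology fidelity (the
lexicon is package-owned).

## Problem sizes and numerical notes

The test suite runs cohorts of 60–1000 patients (the leak scan at 1000,
query/oracle equivalence at 500 patients × 200 randomized definitions,
conservation over 10 seeds at 100 patients, the law-of-large-numbers
check at 10,000) — sizes at which every property is exercised densely
while the whole suite stays fast. The validation corpus is 100 reports,
matching the validation design the measurement mirrors. Survival
comparisons use exact rational arithmetic implicitly (products of small
fractions in double precision) and are asserted to 1e-12; percent fields
round-trip XML exactly because serialization uses shortest-repr decimal
text, never exponent notation.
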