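# Methods

## Exposure model

An administered medication is a *episode*: a patient id, a normalized
generic name, and a closed interval of post-injury days
[`start_day`, `end_day`]. The day of injury is day 1 everywhere; calendar
dates are converted as `day = (date − injury_date) + 1`. The analysis
horizon defaults to 60 days and every window is a closed interval of day
offsets.

A medication *m* is active for patient *i* on day *d* iff some episode of
*m* for *i* satisfies `start ≤ d ≤ end`. All counting is over distinct
normalized names: overlapping episodes of the same generic never double
count, and a patient contributes at most 1 to any per-medication patient
count. This makes three invariants structural rather than empirical:
windowed unique counts are monotone nondecreasing in window length; the
unique count over [1, w] is at least the maximum daily count in that
window; and co-administration edge weights cannot exceed either incident
node weight.

Episodes with a missing end day are treated as single-day administrations
(`missing_end="single_day"`); the alternative (`"censor"`: carry to the
horizon) is a switch because source conventions differ and the conservative
default avoids inflating exposure. Whether an episode that merely overlaps
a window edge counts (default: yes, any overlap) is likewise a flag
(`partial_overlap_counts`) rather than a buried assumption.

### Name normalization

Normalization is lexicon-based (case-fold, whitespace collapse, dose/form/
route token stripping), not a terminology-service lookup: no RxNorm/ATC
resolution is attempted. Combination products are preserved as one distinct
medication — components sorted lexicographically and joined with `+`
(`acetaminophen+oxycodone`) — because splitting them would silently merge
clinically distinct products with their components. The stripping lexicon
is configurable; tokens like `325-5` (strength pairs) are treated as
numeric.

### Ingest and reconciliation

Malformed rows are rejected with machine-readable reason codes
(`end_before_start`, `unknown_patient`, `unparseable_date`,
`start_before_injury`, `empty_name`), never fatally: medication-record
abstraction is noisy and the reconciliation outcome is itself a reported
result. Exact duplicate rows collapse to one episode; rows identical except
dose/frequency/route collapse as dosage-change merges. The validation
report conserves records (`read = accepted + rejected`) by construction.

## Indication classification

Free-text indications map to 27 categories: the 26 System Organ Classes
(the top of the MedDRA hierarchy, as used by the CTCAE) plus
"Trauma-related pain" (nociceptive and neuropathic), added because the
standard classes cover trauma pain poorly. Matching is: exact-string
override table first, then case-insensitive keyword substring scan with
longest-keyword-wins; ties fall to the category listed first in the
vocabulary file, making classification deterministic. Unmatched text is
reported as `unclassified` — in real data, residual indications need
clinician review and forcing them into a category would hide that. The
bundled vocabulary is a curated reconstruction, deliberately replaceable:
licensed MedDRA term-level content below the SOC level is not shipped.

Prophylaxis: an explicit per-row marker wins when present (including an
explicit False); otherwise text stems `prophyla`/`prevent` flag the
episode. "Indications per patient" counts prophylactic administration
records; "medications per patient" counts distinct generics.

## BBB annotation

Three states — `permeable`, `not_permeable`, `unknown` — looked up by
normalized name; absent names are `unknown`, so the three counts always
partition the unique-medication set. The bundled starter table covers
common acute-care drugs and is intended as a seed; a production analysis
should supply a curated table (e.g. compiled from DrugBank plus targeted
literature review). No physicochemical prediction (logP/TPSA) is attempted.

## Co-administration networks

For day *d*: node weight = patients with the medication active on *d*;
edge weight = patients with both active on *d*; edges below
`min_edge_weight` are dropped, zero-weight nodes absent, pair keys stored
lexicographically. Combination rankings support two scopes, because "most
common combination" is ambiguous between a day-specific and a study-period
reading: `day=d` counts co-activity on that day; `window=w` counts a
patient once if the pair is simultaneously active on any day in [1, w].
Simultaneity is required in both — drugs taken on disjoint days never pair,
and never-co-active pairs are omitted from rankings (they are not
enumerable in general). Only pairwise edges are built; higher-order
combinations are available as per-patient daily sets rather than
hyperedges.

## Summaries and rounding

Percentages and reported means are rounded half away from zero to one
decimal, and percentage denominators are always the full cohort including
missing (642 males of 797 → 80.6%). Missing values are their own category,
so per-variable counts sum to the cohort size. Window summaries print as
`mean ± SD (range lo–hi)` with sample (n−1) SD; with one patient the SD is
NA. Cross-source medication overlap uses exact inclusion–exclusion.
Inclusion filters exclude AIS grade E everywhere and zero-episode patients
only in cohorts flagged as record-abstraction-based (an empty log there
means missing data, not zero exposure); patients matching both reasons are
tallied once, under missing data. Left-truncation from late enrollment is
*not* imputed: days before first capture simply show zero exposure, and the
observational/trial disparity in early windows is the visible signature of
capture, not of treatment.

## Synthetic cohort generator

The generator defines the test-bench conditions:

- **Demographics** (defaults, per patient, independent): sex 80% male /
  19.3% female / 0.7% missing; AIS A 52.5%, B 12%, C 18.5%, D 11%, unknown
  6%; level cervical 67% / thoracic 15% / lumbar 17% / unknown 1%; causes
  dominated by automobile (42%) and falls (20%); age ~ N(33, 14²) clipped
  to [12, 89]. Tetraplegia is derived from cervical level.
- **Episode process**: episode count ~ Poisson(λ) with λ = 44 (AIS A/B),
  36 (C), 26 (D), 36 (unknown) over the 60-day horizon; medication drawn
  i.i.d. from a 100-entry catalog with Zipf(0.8) popularity weights (the
  head uses real generic names — acetaminophen, morphine, heparin,
  docusate, acetaminophen+oxycodone, … — so outputs read naturally; the
  tail is synthetic names); start day from a mixture of 65% discretized
  exponential (scale 5 d, acute care) and 35% discretized normal
  (30 ± 14 d, rehabilitation), truncated to the horizon; duration from a
  geometric mixture (85% mean 3 d, 15% mean 21 d) capturing short courses
  with occasional long continuous use.
- **Capture**: trial flavor enrolls uniformly on days 1–3; observational
  flavor at `max(1, round(N(30, 27²)))`. Episodes ending before enrollment
  are unobserved; straddling episodes are captured from enrollment on. The
  latent record is emitted as ground truth, so censoring tests never
  re-derive truth from the pipeline under test.

Because the episode count is Poisson and medications/starts/durations are
i.i.d., Poisson thinning gives a closed form for the expected number of
distinct medications active on day *d* per patient:
`E = Σ_g π_g Σ_m (1 − exp(−λ_g · w_m · p_d))`, with `p_d` the per-episode
activity probability computed exactly from the start pmf and duration
survival. Parameter-recovery tests check the simulated latent mean daily
prevalence against this expectation (within 3 standard errors at n=200–300)
and check that uncensored runs give exact identity between latent and
pipeline-estimated window means.

Defaults produce trial-flavor 7/60-day unique-count means around 14/26
with daily concurrent counts reaching the high teens — the right order of
magnitude and ordering (severity gradient A/B > D; observational ≪ trial in
early windows) for an acute-SCI cohort, but deliberately *not* calibrated
to any specific study's figures: the generator validates machinery, not
clinical estimates. What passing tests show is that the arithmetic is
exact, the invariants hold, and configured effects are recovered with the
correct sign and magnitude; they say nothing about how any real cohort was
treated. Real data differ in ways the generator does not model: drug-
specific durations and co-prescription correlations (order sets), dose
changes over time, within-patient autocorrelation of episode starts,
transfers and re-admissions, and messy free-text names.

## Problem sizes and numerical choices

Oracle-equivalence tests compare against brute-force day-grid scans on 200
random cohorts of up to 50 patients; structural invariants run on 80-
patient synthetic cohorts and recovery on 200–500; the full suite completes
in a few seconds. Determinism is end-to-end: a fixed (config, seed) yields
byte-identical cohorts and reports (JSON written with sorted keys; ranking
ties broken by count then lexicographic name). Degenerate inputs are
contracts, not accidents: empty medication logs are valid (empty list plus
report), empty cohorts raise, single-patient SD is NA, day queries outside
the horizon raise.

## Known limitations

No dose-intensity weighting, defined-daily-dose, or adherence modelling;
no drug–drug interaction detection; no statistical testing between strata
(the analysis is descriptive); classification quality is bounded by the
supplied lexicon; the starter BBB table is illustrative, not authoritative.
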