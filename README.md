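# polypharm

Drug-exposure reconstruction and polypharmacy analysis for acute spinal
cord injury (SCI) medication logs.

Acute traumatic SCI affects every organ system, and its management draws on
analgesics, anticoagulants, antibiotics, anticonvulsants, sympathomimetics
and more — often many at once, during the very window in which neural
repair and plasticity are possible. Several of these drugs cross the
blood–brain barrier and may modify neurological recovery. `polypharm` turns
raw concomitant-medication logs (one row per administered medication with a
start/end interval, dose, route and free-text indication) into the
descriptive epidemiology of that exposure:

- **day-level exposure**: for each patient, the set of distinct medications
  active on each post-injury day *d* (day of injury = day 1, closed
  intervals), i.e. the point prevalence *n<sub>i</sub>(d) = |{m : some
  episode of m satisfies start ≤ d ≤ end}|*;
- **windowed unique-medication counts**: per patient, the number of
  distinct generics with any exposure in days [1, w] for w ∈ {7, 14, 30,
  60}, summarized as mean ± SD (range) with sample (n−1) SD;
- **polypharmacy summaries**: per-day mean/min/max medication counts,
  stratified by injury severity (AIS grade), with missing grades kept as
  their own "unknown" stratum;
- **indication → organ-system classification**: lexicon-based assignment of
  free-text indications to the 26 System Organ Classes (the top level of
  the MedDRA hierarchy, as used by the CTCAE) plus an added trauma-related
  pain category, with prophylactic use flagged from explicit markers or the
  stems "prophyla-"/"prevent-";
- **blood–brain-barrier annotation**: three-state (permeable / not
  permeable / unknown) lookup over the unique-medication set;
- **co-administration networks**: for a chosen day, nodes weighted by
  patients exposed and edges by patients with both drugs active, exported
  as TSV edge lists and GraphML;
- **cohort summaries**: Table-1-style demographics, inclusion filters
  (AIS E; missing medication data in record-abstraction cohorts), and
  cross-source unique-medication overlap by inclusion–exclusion.

Because such clinical records are typically not public, the package ships a
seeded synthetic cohort generator (`polypharm.synth`) that emulates the
study-shaped structure — 4:1 male:female, AIS-A-majority, cervical-dominant
cohorts; severity-dependent episode intensity; an early-enrolling "trial"
capture flavor versus an "observational" flavor whose records start at
rehabilitation admission (~30 ± 27 days post-injury) — together with the
latent ground truth and a closed-form expectation of mean daily exposure,
so every pipeline stage is testable end to end.

Intended users: pharmacoepidemiologists and clinical researchers analyzing
concomitant-medication case-report forms or abstracted medication records,
and methodologists who need a reproducible, property-tested reference for
exposure-interval arithmetic.

## Worked example

```python
from polypharm import (SyntheticConfig, simulate_cohort, unique_meds_in_window,
                       window_summary, daily_exposure, rank_combinations)

patients, episodes, _ = simulate_cohort(SyntheticConfig(n_patients=200, seed=7))
pids = [p.patient_id for p in patients]
for w in (7, 14, 30, 60):
    print(w, window_summary(unique_meds_in_window(episodes, w, pids), w).format())
daily = daily_exposure(episodes, 60, pids)
print(rank_combinations(daily, k=3, window=60))
```

prints

```
7 14.6 ± 3.7 (range 7–25)
14 18.5 ± 4.0 (range 8–29)
30 22.5 ± 4.6 (range 10–34)
60 26.1 ± 4.9 (range 12–40)
[(('acetaminophen', 'morphine'), 160),
 (('acetaminophen', 'acetaminophen+oxycodone'), 141),
 (('acetaminophen', 'acetaminophen+hydrocodone'), 120)]
```

— the per-patient count of distinct medications in the first 7/14/30/60
days (monotone by construction; "mean ± SD (range lo–hi)"), and the drug
pairs most often active simultaneously in the same patient. Note that
combination products (e.g. `acetaminophen+oxycodone`) are a single distinct
medication, never split into components.

The `examples/` directory contains one short script per capability
(simulation, exposure, classification, BBB, networks, full pipeline); each
prints what it computes and what the numbers mean. The `polypharm` CLI
(`simulate`, `ingest`, `exposure`, `soc`, `bbb`, `network`, `report`,
`run`) wires the same functions into a reproducible pipeline with a run
manifest.

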