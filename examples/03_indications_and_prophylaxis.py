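"""Classify free-text indications into organ-system categories.

Indications are mapped to the 26 System Organ Classes (top level of the
MedDRA hierarchy, as used by the CTCAE) plus an added trauma-related pain
category; prophylactic administrations are flagged from markers or text.
"""

from polypharm import (
    SOCVocabulary,
    SyntheticConfig,
    classify_episodes,
    classify_indication,
    prophylaxis_summary,
    simulate_cohort,
    soc_summary,
)

vocab = SOCVocabulary.default()
for text in ("urinary tract infection", "neuropathic pain", "DVT prophylaxis", "zzz-unknown"):
    a = classify_indication(text, vocab)
    print(f"{text!r:<28} -> {a.category} (method={a.method}, prophylactic={a.prophylactic})")

patients, episodes, _ = simulate_cohort(SyntheticConfig(n_patients=150, seed=11))
assignments = classify_episodes(episodes, vocab)
table = soc_summary(episodes, assignments, vocab, cohort_size=len(patients))
print("\nbusiest organ-system categories (patients treated):")
print(table.sort_values("n_patients", ascending=False).head(6).to_string())

proph = prophylaxis_summary(episodes, assignments, cohort_size=len(patients))
print(f"\nprophylaxis: {proph.n_patients} patients ({proph.pct_patients}%), {proph.format()}")
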