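"""Stage a small questionnaire panel and summarise it.

Builds a toy three-wave panel from raw (motivation, smoked-past-7-days)
items, applies complete-case exclusion and relapse censoring, and
prints the interval transition counts and observed prevalence. The
percentages are counts over the arm size; the change row is week 26
minus week 0.
"""

import stageflow as sf

records = []
# five subjects: one missing a wave, one showing a relapse out of
# abstinence (both handled by the exclusion/censoring steps)
raw = {
    "s1": {0: (2, "yes"), 12: (5, "yes"), 26: (9, "yes")},
    "s2": {0: (1, "yes"), 12: (None, "no"), 26: (None, "no")},
    "s3": {0: (3, "yes"), 12: (4, "yes")},          # missing week 26
    "s4": {0: (0, "yes"), 12: (None, "no"), 26: (2, "yes")},  # relapse
    "s5": {0: (6, "yes"), 12: (8, "yes"), 26: (None, "no")},
}
for sid, waves in raw.items():
    for week, (motivation, smoked) in waves.items():
        records.append(sf.StageRecord(
            subject_id=sid, group="DEMO", week=week,
            motivation=motivation, smoked_past7=(smoked != "no"),
        ))

panel = sf.build_panel(records, grid=(0, 12, 26), complete_case=True)
panel = sf.censor_relapse(panel)

print("retained subjects:", panel.n_subjects())
print("dropped:", panel.exclusion_log["dropped_subjects"])
print("relapse transitions removed:",
      panel.exclusion_log["relapse"]["transitions_removed"])

counts = sf.transition_counts(panel, "DEMO")
print(f"\ninterval transition counts (design interval {counts.interval} weeks):")
print(counts.to_frame())

print("\nobserved prevalence (counts n1..n4, percentages p1..p4):")
print(sf.observed_prevalence(panel).round(1).to_string(index=False))
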