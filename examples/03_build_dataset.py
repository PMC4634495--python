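"""Build a labelled day-level dataset from a synthetic feature cohort.

Shows the labelling rules: each exacerbation onset and its 7 preceding
days are positive (the prodrome), the 14 days after the onset are masked
as recovery, and daily features are smoothed with a trailing 14-day
window before labelling.
"""

from aecopd import CohortParams, synth_cohort_features, assemble

params = CohortParams(n_patients=3, n_days=90, events_per_patient=1,
                      effect_size=1.5, seed=5)
feats, events = synth_cohort_features(params)
ds = assemble(feats, events)

print(f"patients: {params.n_patients}, monitored days: {len(ds.rows)}")
print(f"valid days: {int(ds.rows['valid'].sum())} "
      f"(recovery-masked: {int((~ds.rows['valid']).sum())})")
print(f"prodromal (positive) days: {int(ds.rows['label'].sum())}")
for ev in events:
    sub = ds.rows[ds.rows.patient_id == ev.patient_id]
    pos_days = sub.loc[sub.label == 1, "day_index"].tolist()
    print(f"  {ev.patient_id}: onset day {ev.onset_day}, "
          f"positive days {pos_days}")
# Each clean event contributes up to 8 positive days (onset + 7 before,
# minus any missing recordings) and masks the following 14 days.
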