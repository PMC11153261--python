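"""Consistency of subgroup membership over 8 years of follow-up.

Windowed indicators ([0,2), [2,4), [4,6), [6,8) years; C-peptide carried
forward from baseline) are re-assigned by (1) de novo re-clustering and
(2) nearest-baseline-centre reallocation, and compared with the baseline
partition. Treatment lowers HbA1c sharply in the severe insulin-deficient
subgroup, so SIDD members migrate toward the mild subgroups.
"""

import t2dsubgroups as t

params = t.default_params("DCS", n_individuals=800, seed=3)
cohort, _ = t.simulate_cohort(params)
cohort, _ = t.apply_inclusion_criteria(cohort)
baseline = t.select_baseline(cohort)
model, idx = t.fit_subgroups(baseline, seed=1)
model = t.name_clusters(model, t.registry_reference_centres("DCS"))
labels = t.cluster_labels_named(model, idx)

windows = t.WindowSpec()
wtable = t.window_indicators(cohort, windows, baseline)

for name, labs in (("de novo re-clustering", t.denovo_reallocate(wtable, model, seed=1)[0]),
                   ("centre-based reallocation", t.centre_reallocate(wtable, model))):
    reports, trend = t.consistency_report(labels, labs)
    accs = {w: round(r.accuracy, 3) for w, r in reports.items()}
    print(f"{name}: accuracy by window {accs} (relative change {trend:+.1%})")

centre = t.centre_reallocate(wtable, model)
transitions = t.enumerate_transitions(centre)
print(f"\ntop 3 trajectories over {transitions.n_complete} fully observed individuals:")
print(transitions.top.head(3)[["trajectory", "count"]].to_string(index=False))
print("\nstay fraction per baseline subgroup (1.0 = never leaves):")
print(transitions.stay_fraction.round(2).to_string())

movement = t.severe_mild_movement(labels, centre["[2,4)"])
print("\nsevere/mild movement, baseline -> [2,4):",
      movement.value_counts().to_dict())

# Centre-based reallocation is typically the more stable of the two methods,
# and SIDD shows the lowest stay fraction: its treated HbA1c decline moves
# members into the mild subgroups.
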