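"""Time to diabetes complications by subgroup, with delayed entry.

Cumulative incidence is 1 - Kaplan-Meier survival on the diabetes-duration
scale, with individuals entering the risk set at their baseline visit.
Pairwise logrank tests use Benjamini-Hochberg correction; Cox hazard ratios
use the mild-with-high-HDL subgroup (MDH) as reference, with Schoenfeld
tests flagging proportional-hazards violations.
"""

import warnings

warnings.filterwarnings("ignore")

import t2dsubgroups as t

params = t.default_params("DCS", n_individuals=4000, seed=13)
cohort, _ = t.simulate_cohort(params)
cohort, _ = t.apply_inclusion_criteria(cohort)
baseline = t.select_baseline(cohort)
model, idx = t.fit_subgroups(baseline, seed=4)
model = t.name_clusters(model, t.registry_reference_centres("DCS"))
labels = t.cluster_labels_named(model, idx)
entry = baseline.set_index("id")["baseline_duration"]

events = cohort.events[cohort.events["outcome"] == "AMI"]
curves = t.km_cumulative_incidence(events, labels, eval_time=10.0,
                                   entry_times=entry, outcome="AMI")
print("AMI cumulative incidence at 10 years since diagnosis:")
for s in t.SUBGROUPS:
    print(f"  {s:>4}: {curves[s].value_at_eval:.1%}")

lr = t.logrank_pairwise(events, labels, entry_times=entry)
print(f"\nglobal logrank p = {lr['global_p']:.4f}")
print("BH-adjusted SIRD-vs-MDH pairwise p =",
      f"{lr['adjusted'].loc['SIRD', 'MDH']:.4f}")

cov = baseline.set_index("id")[["sex", "age"]].copy()
cov["subgroup"] = labels
for adjust in ("none", "age_sex"):
    res = t.fit_cox(events, cov, entry_times=entry, adjust=adjust)
    hr = res.summary.loc["subgroup_SIRD"]
    flag = " (PH violated)" if hr["ph_violated"] else ""
    print(f"Cox ({adjust:7}): SIRD vs MDH HR {hr['HR']:.2f} "
          f"[{hr['HR_lower95']:.2f}, {hr['HR_upper95']:.2f}]{flag}")

# The generator gives SIRD an AMI log-hazard offset of ln(1.65) over MDH. The
# fitted HR sits a little below that: clusters overlap, so some fitted-SIRD
# members are not true SIRD, which attenuates the contrast toward 1.
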