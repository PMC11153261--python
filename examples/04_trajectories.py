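"""Risk-factor trajectories by subgroup.

Annual means with SD bands describe each subgroup's progression; the
random-intercept model quantifies between-subgroup differences while
absorbing each individual's own level. The severe insulin-resistant
subgroup is configured with elevated blood creatinine, which the model's
SIRD-vs-SIDD contrast should recover.
"""

import warnings

warnings.filterwarnings("ignore")

import t2dsubgroups as t

params = t.default_params("DCS", n_individuals=800, seed=21)
cohort, _ = t.simulate_cohort(params)
cohort, _ = t.apply_inclusion_criteria(cohort)
baseline = t.select_baseline(cohort)
model, idx = t.fit_subgroups(baseline, seed=2)
model = t.name_clusters(model, t.registry_reference_centres("DCS"))
labels = t.cluster_labels_named(model, idx)

summary = t.annual_summary(cohort, "creatinine", labels)
year5 = summary[summary["year"] == 5].set_index("subgroup")
print("creatinine at year 5 (mean ± SD, µmol/l):")
for s in t.SUBGROUPS:
    if s in year5.index:
        r = year5.loc[s]
        print(f"  {s:>4}: {r['mean']:6.1f} ± {r['sd']:.1f}  (n={r['n']})")

res = t.fit_random_intercept(cohort, "creatinine", "subgroups", labels,
                             reference_subgroup="SIDD")
est = res.params["subgroup_SIRD"]
se = res.bse["subgroup_SIRD"]
print(f"\nrandom-intercept model (ML): SIRD vs SIDD creatinine difference "
      f"{est:.2f} ± {se:.2f} µmol/l")
print(f"random-intercept SD {res.random_intercept_var**0.5:.2f}, "
      f"residual SD {res.residual_var**0.5:.2f}, AIC {res.aic:.1f}")

# The contrast should sit near the configured mean separation
# (87.15 - 77.40 ~ 9.8 umol/l at baseline) plus any drift difference;
# the generator, not the registry, defines the truth here.
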