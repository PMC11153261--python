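import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines.statistics import multivariate_logrank_test

import t2dsubgroups as t
from t2dsubgroups.outcomes import schoenfeld_ph_test


def _events(times, observed, ids=None):
    ids = ids or [f"i{k}" for k in range(len(times))]
    return pd.DataFrame({"id": ids, "outcome": "AMI", "time": times,
                         "observed": observed})


class TestKM:
    def test_no_censoring_equals_ecdf(self):
        ev = _events([1.0, 2.0, 3.0, 4.0], [True] * 4)
        groups = pd.Series("g", index=ev["id"])
        curves = t.km_cumulative_incidence(ev, groups, eval_time=2.5)
        assert curves["g"].value_at_eval == pytest.approx(0.5)

    def test_all_censored_is_zero(self):
        ev = _events([1.0, 2.0, 3.0], [False] * 3)
        groups = pd.Series("g", index=ev["id"])
        curves = t.km_cumulative_incidence(ev, groups, eval_time=10.0)
        assert curves["g"].value_at_eval == 0.0
        assert np.all(curves["g"].cumulative_incidence == 0.0)

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(8)
        n = 5000
        times = rng.exponential(10.0, size=n)  # lambda = 0.1
        ev = _events(np.minimum(times, 30.0), times <= 30.0)
        groups = pd.Series("g", index=ev["id"])
        curves = t.km_cumulative_incidence(ev, groups, eval_time=10.0)
        assert curves["g"].value_at_eval == pytest.approx(1 - np.exp(-1), abs=0.02)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1.0, 2.0, 3.0, 4.0]
        ev = _events(times * 2, [True] * 8)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=ev["id"])
        stat, p = t.logrank_test(ev, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_lifelines_without_entry(self):
        rng = np.random.default_rng(5)
        n = 300
        times = rng.exponential(5.0, size=n)
        cens = rng.exponential(8.0, size=n)
        ev = _events(np.minimum(times, cens), times <= cens)
        groups = pd.Series(rng.choice(["a", "b", "c"], size=n), index=ev["id"])
        stat, p = t.logrank_test(ev, groups)
        ref = multivariate_logrank_test(ev["time"], groups.to_numpy(),
                                        ev["observed"].astype(int))
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_pairwise_structure_and_flags(self, fitted):
        ev = fitted["cohort"].events
        ev = ev[ev["outcome"] == "CKD"]
        res = t.logrank_pairwise(ev, fitted["labels"], entry_times=fitted["entry"])
        assert res["raw"].shape == (5, 5)
        offdiag = ~np.eye(5, dtype=bool)
        assert res["adjusted"].to_numpy()[offdiag].min() >= res["raw"].to_numpy()[offdiag].min()
        assert 0 <= res["global_p"] <= 1


class TestBH:
    def test_single_and_equal(self):
        assert t.bh_adjust([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(t.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_step_up_example(self):
        np.testing.assert_allclose(t.bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            t.bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    def test_matches_min_over_tail_definition(self, pvals):
        p = np.asarray(pvals)
        adj = t.bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        oracle = np.empty(m)
        for rank_pos, idx in enumerate(order):
            tail = [min(1.0, p[order[j]] * m / (j + 1)) for j in range(rank_pos, m)]
            oracle[idx] = min(tail)
        np.testing.assert_allclose(adj, oracle, atol=1e-15)


class TestCox:
    def _two_group(self, seed=0, n=2000, hr=2.0):
        rng = np.random.default_rng(seed)
        grp = rng.integers(0, 2, size=n)
        lam = 0.05 * hr**grp
        entry = rng.uniform(0, 0.5, size=n)
        times = entry + rng.exponential(1 / lam)
        cens = entry + rng.exponential(1 / 0.02, size=n)
        cens = np.minimum(cens, 25.0)
        ids = [f"i{k}" for k in range(n)]
        ev = pd.DataFrame({"id": ids, "outcome": "AMI",
                           "time": np.minimum(times, cens),
                           "observed": times <= cens})
        cov = pd.DataFrame({"x": grp.astype(float)}, index=ids)
        return ev, cov, pd.Series(entry, index=ids)

    def test_recovery_with_delayed_entry(self):
        ev, cov, entry = self._two_group(seed=1)
        res = t.fit_cox(ev, cov, entry_times=entry)
        coef, se = res.summary.loc["x", "coef"], res.summary.loc["x", "se"]
        assert abs(coef - np.log(2)) < 3 * se

    def test_time_scale_invariance(self):
        ev, cov, entry = self._two_group(seed=2, n=500)
        r1 = t.fit_cox(ev, cov, entry_times=entry)
        ev2 = ev.assign(time=ev["time"] * 7.3)
        r2 = t.fit_cox(ev2, cov, entry_times=entry * 7.3)
        assert r1.summary.loc["x", "coef"] == pytest.approx(
            r2.summary.loc["x", "coef"], abs=1e-6)

    def test_constant_covariate_dropped(self):
        ev, cov, entry = self._two_group(seed=3, n=300)
        cov["flat"] = 1.0
        res = t.fit_cox(ev, cov, entry_times=entry)
        assert "flat" not in res.summary.index

    def test_no_events_error(self):
        ev = _events([1.0, 2.0], [False, False])
        cov = pd.DataFrame({"x": [0.0, 1.0]}, index=ev["id"])
        with pytest.raises(ValueError, match="no observed events"):
            t.fit_cox(ev, cov)

    def test_subgroup_contrasts_vs_reference(self, fitted):
        ev = fitted["cohort"].events
        ev = ev[ev["outcome"] == "CKD"]
        cov = fitted["baseline"].set_index("id")[["sex", "age"]].copy()
        cov["subgroup"] = fitted["labels"]
        res = t.fit_cox(ev, cov, entry_times=fitted["entry"], adjust="age_sex")
        assert res.reference == "MDH"
        assert "subgroup_MDH" not in res.summary.index
        assert {"subgroup_SIDD", "subgroup_SIRD", "subgroup_MOD",
                "subgroup_MD", "age", "sex_M"} <= set(res.summary.index)
        hr = res.summary["HR"]
        assert ((res.summary["HR_lower95"] <= hr) & (hr <= res.summary["HR_upper95"])).all()


def test_configured_sird_ami_hazard_recovered():
    """The generator's SIRD-vs-MDH AMI log-hazard offset of ln(1.65) is
    recovered by the unadjusted left-truncated Cox fit on true labels
    (single large replicate in place of a 200-replicate coverage study,
    to keep the suite fast)."""
    params = t.default_params("DCS", n_individuals=12000, seed=99)
    cohort, truth = t.simulate_cohort(params)
    base = t.select_baseline(cohort)
    entry = base.set_index("id")["baseline_duration"]
    ev = cohort.events[cohort.events["outcome"] == "AMI"]
    cov = base.set_index("id")[["sex", "age"]].copy()
    cov["subgroup"] = truth.set_index("id")["subgroup"]
    res = t.fit_cox(ev, cov, entry_times=entry)
    coef = res.summary.loc["subgroup_SIRD", "coef"]
    se = res.summary.loc["subgroup_SIRD", "se"]
    assert abs(coef - np.log(1.65)) < 3 * se


class TestSchoenfeld:
    def test_matches_lifelines_without_entry(self):
        from lifelines import CoxPHFitter
        from lifelines.statistics import proportional_hazard_test
        rng = np.random.default_rng(11)
        n = 400
        x = rng.normal(size=(n, 2))
        T = rng.exponential(1 / np.exp(0.4 * x[:, 0]))
        C = rng.exponential(2.0, size=n)
        df = pd.DataFrame({"time": np.minimum(T, C), "observed": (T <= C).astype(int),
                           "x0": x[:, 0], "x1": x[:, 1]})
        cph = CoxPHFitter().fit(df, "time", "observed")
        ref = proportional_hazard_test(cph, df, time_transform="rank")
        mine = schoenfeld_ph_test(df["time"], df["observed"], np.zeros(n),
                                  df[["x0", "x1"]], cph.params_.to_numpy())
        np.testing.assert_allclose(mine.to_numpy(),
                                   ref.summary["p"].to_numpy(), atol=1e-10)

    def test_detects_reversing_effect(self):
        """A hazard ratio that reverses mid-follow-up violates PH and the
        diagnostic flags it."""
        rng = np.random.default_rng(12)
        n = 2000
        grp = rng.integers(0, 2, size=n)
        # group 1 hazard is 2x before t=5 and 0.5x after
        t1 = rng.exponential(1 / (0.2 * 2.0**grp))
        t2 = 5.0 + rng.exponential(1 / (0.2 * 0.5**grp))
        times = np.where(t1 < 5.0, t1, t2)
        ev = pd.DataFrame({"id": range(n), "time": times,
                           "observed": np.ones(n, dtype=bool)})
        cov = pd.DataFrame({"x": grp.astype(float)}, index=range(n))
        res = t.fit_cox(ev.assign(outcome="AMI"), cov)
        assert res.summary.loc["x", "schoenfeld_p"] < 0.05
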