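from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import cohen_kappa_score

import t2dsubgroups as t
from t2dsubgroups.constants import INDICATORS, SUBGROUPS
from t2dsubgroups.subgrouping import reference_centres_scaled


def _toy_baseline():
    # two individuals per sex, hand-checkable values
    return pd.DataFrame({
        "id": ["m1", "m2", "f1", "f2"],
        "sex": ["M", "M", "F", "F"],
        "age": [50.0, 60.0, 55.0, 65.0],
        "bmi": [28.0, 32.0, 27.0, 33.0],
        "hba1c": [40.0, 60.0, 45.0, 55.0],
        "c_peptide": [0.8, 1.2, 0.9, 1.1],
        "hdl": [1.0, 1.4, 1.1, 1.3],
    })


class TestScaling:
    def test_hand_computed_sample_sd(self):
        scaling = t.compute_scaling(_toy_baseline())
        i = INDICATORS.index("hba1c")
        assert scaling.location["M"][i] == pytest.approx(50.0)
        assert scaling.scale["M"][i] == pytest.approx(np.sqrt(200.0))

    def test_zscore_identity_on_own_sample(self, fitted):
        base = fitted["baseline"]
        scaling = t.compute_scaling(base)
        for sex, grp in base.groupby("sex"):
            z = np.vstack([t.scale_indicators(row[list(INDICATORS)], sex, scaling)
                           for _, row in grp.iterrows()])
            np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-10)
            np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_sex_stratification(self):
        base = _toy_baseline()
        scaling_all = t.compute_scaling(base)
        more_males = pd.concat([base, pd.DataFrame({
            "id": ["m3"], "sex": ["M"], "age": [70.0], "bmi": [40.0],
            "hba1c": [90.0], "c_peptide": [2.0], "hdl": [2.0]})],
            ignore_index=True)
        scaling_more = t.compute_scaling(more_males)
        np.testing.assert_array_equal(scaling_all.location["F"], scaling_more.location["F"])
        np.testing.assert_array_equal(scaling_all.scale["F"], scaling_more.scale["F"])

    def test_zero_variance_named(self):
        base = _toy_baseline()
        base["hdl"] = 1.0
        with pytest.raises(ValueError, match="hdl"):
            t.compute_scaling(base)

    def test_scale_round_trip(self):
        scaling = t.compute_scaling(_toy_baseline())
        raw = np.array([57.0, 30.0, 70.0, 1.0, 1.2])
        z = t.scale_indicators(raw, "F", scaling)
        np.testing.assert_allclose(scaling.inverse(z, "F"), raw, rtol=1e-12)

    def test_vectors_at_location_and_plus_one_sd(self):
        scaling = t.compute_scaling(_toy_baseline())
        loc, sd = scaling.location["M"], scaling.scale["M"]
        np.testing.assert_allclose(t.scale_indicators(loc, "M", scaling), 0.0, atol=1e-12)
        np.testing.assert_allclose(t.scale_indicators(loc + sd, "M", scaling), 1.0, rtol=1e-12)

    def test_missing_component_rejected(self):
        scaling = t.compute_scaling(_toy_baseline())
        with pytest.raises(ValueError):
            t.scale_indicators([50.0, 30.0, np.nan, 1.0, 1.2], "M", scaling)


class TestFitSubgroups:
    def test_label_recovery_well_separated(self, wellsep):
        rep = t.compare_partitions(wellsep["truth"].loc[wellsep["labels"].index],
                                   wellsep["labels"])
        assert rep.accuracy >= 0.99

    def test_duplication_invariance(self, wellsep):
        """Duplicating every individual leaves the partition unchanged and
        the centres equal up to the ddof=1 sample-SD effect (O(1/n))."""
        base = wellsep["baseline"]
        dup = pd.concat([base, base.assign(id=base["id"] + "_copy")],
                        ignore_index=True)
        m1, idx1 = t.fit_subgroups(base, seed=2)
        m2, idx2 = t.fit_subgroups(dup, seed=2)
        c1 = m1.centres[np.lexsort(m1.centres.T)]
        c2 = m2.centres[np.lexsort(m2.centres.T)]
        np.testing.assert_allclose(c1, c2, atol=0.01)
        # partition of the original ids is identical up to cluster relabelling
        joint = pd.crosstab(idx1, idx2.loc[idx1.index])
        assert (joint.to_numpy() > 0).sum() == 5

    def test_determinism(self, fitted):
        m2, idx2 = t.fit_subgroups(fitted["baseline"], seed=3)
        np.testing.assert_array_equal(m2.centres, fitted["model"].centres)

    def test_small_stratum_rejected(self):
        with pytest.raises(ValueError, match="fewer than k"):
            t.fit_subgroups(_toy_baseline())

    def test_pooled_centres_are_member_means(self, fitted):
        """Re-verify the centre definition: arithmetic mean of all member
        scaled vectors, both sexes pooled."""
        base, model = fitted["baseline"], fitted["model"]
        _, idx = t.fit_subgroups(base, seed=3)
        from t2dsubgroups.subgrouping import _scaled_matrix
        z = _scaled_matrix(base, model.scaling)
        for c in range(5):
            members = z[(idx.to_numpy() == c)]
            np.testing.assert_allclose(model.centres[c], members.mean(axis=0),
                                       atol=1e-10)

    def test_fixed_point_on_separated_data(self, wellsep):
        """Nearest-centre assignment of the fitting sample reproduces the
        fitted partition when clusters are well separated."""
        realloc = t.assign_table(wellsep["baseline"], wellsep["model"])
        agree = (realloc == wellsep["labels"].loc[realloc.index]).mean()
        assert agree == 1.0


class TestNaming:
    def _model(self, centres, seed_scaling):
        return t.ClusterModel(scaling=seed_scaling, centres=centres,
                              names=None)

    def test_identity_and_swap(self, fitted):
        model = fitted["model"]
        named = t.name_clusters(
            t.ClusterModel(model.scaling, model.centres),
            model.centres, reference_names=model.names)
        assert named.names == model.names
        assert named.metadata["naming_total_distance"] == pytest.approx(0.0)
        # swap two reference rows: the swap must be recovered
        perm = list(range(5))
        perm[0], perm[3] = perm[3], perm[0]
        named2 = t.name_clusters(
            t.ClusterModel(model.scaling, model.centres),
            model.centres[perm], reference_names=[model.names[p] for p in perm])
        assert named2.names == model.names

    def test_optimal_vs_exhaustive(self):
        """Assignment cost equals the brute-force minimum over all 120
        permutations on random centre sets."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            fitted_c = rng.normal(size=(5, 5))
            ref = rng.normal(size=(5, 5))
            dist = np.linalg.norm(fitted_c[:, None] - ref[None], axis=2)
            rows, cols = linear_sum_assignment(dist)
            optimal = dist[rows, cols].sum()
            brute = min(sum(dist[i, p[i]] for i in range(5))
                        for p in permutations(range(5)))
            assert optimal == pytest.approx(brute, rel=1e-12)

    def test_wrong_reference_count(self, fitted):
        with pytest.raises(ValueError):
            t.name_clusters(t.ClusterModel(fitted["model"].scaling,
                                           fitted["model"].centres),
                            fitted["model"].centres[:4],
                            reference_names=SUBGROUPS[:4])


class TestAssignment:
    def test_exact_centre_is_assigned(self, fitted):
        model = fitted["model"]
        md = model.centres[model.names.index("MD")]
        raw = model.scaling.inverse(md, "F")
        assert t.assign_nearest_centre(raw, "F", model) == "MD"

    def test_published_mean_vectors_name_themselves(self):
        """Centres built from the five published DCS subgroup mean vectors
        assign each raw mean vector to its own subgroup (zero distance)."""
        ref = t.registry_reference_centres("DCS")
        scaling = t.ScalingParams(
            location={s: np.array([55.0, 30.0, 55.0, 1.0, 1.1]) for s in ("M", "F")},
            scale={s: np.array([8.0, 4.0, 12.0, 0.4, 0.25]) for s in ("M", "F")},
        )
        centres = reference_centres_scaled(ref, scaling)
        model = t.ClusterModel(scaling, centres, names=list(ref.index))
        sidd_raw = ref.loc["SIDD"].to_numpy()  # age 57.32, BMI 29.10, HbA1c 89.94 ...
        assert t.assign_nearest_centre(sidd_raw, "M", model) == "SIDD"
        for name in SUBGROUPS:
            assert t.assign_nearest_centre(ref.loc[name].to_numpy(), "M", model) == name

    def test_invariance_to_common_rescaling(self, fitted):
        """Multiplying every scaled axis by the same positive constant leaves
        nearest-centre assignments unchanged."""
        model = fitted["model"]
        c = 3.7
        scaled_model = t.ClusterModel(
            t.ScalingParams({s: v for s, v in model.scaling.location.items()},
                            {s: v / c for s, v in model.scaling.scale.items()}),
            model.centres * c, names=model.names)
        a1 = t.assign_table(fitted["baseline"], model)
        a2 = t.assign_table(fitted["baseline"], scaled_model)
        assert (a1 == a2).all()


def test_model_yaml_round_trip(tmp_path, fitted):
    path = tmp_path / "model.yaml"
    t.save_model(fitted["model"], path)
    back = t.load_model(path)
    np.testing.assert_array_equal(back.centres, fitted["model"].centres)
    assert back.names == fitted["model"].names
    a1 = t.assign_table(fitted["baseline"], fitted["model"])
    a2 = t.assign_table(fitted["baseline"], back)
    assert (a1 == a2).all()


class TestComparePartitions:
    def test_identical_sequences(self):
        labels = ["SIDD", "MD", "MD", "SIRD", "MDH"] * 4
        rep = t.compare_partitions(labels, labels)
        assert rep.accuracy == 1.0 and rep.kappa == 1.0
        assert (rep.per_class.dropna() == 1.0).all().all()

    def test_chance_agreement(self):
        rep = t.compare_partitions(["a", "a", "b", "b"], ["a", "b", "a", "b"])
        assert rep.accuracy == pytest.approx(0.5)
        assert rep.kappa == pytest.approx(0.0)

    def test_against_direct_summation_oracle(self):
        rng = np.random.default_rng(7)
        classes = list(SUBGROUPS)
        ref = rng.choice(classes, size=200)
        cand = rng.choice(classes, size=200)
        rep = t.compare_partitions(ref, cand, classes=classes)
        # independent direct-summation oracle
        n = len(ref)
        p_o = np.mean(ref == cand)
        p_e = sum((np.mean(ref == c)) * (np.mean(cand == c)) for c in classes)
        kappa = (p_o - p_e) / (1 - p_e)
        assert rep.kappa == pytest.approx(kappa, abs=1e-12)
        assert rep.kappa == pytest.approx(cohen_kappa_score(ref, cand), abs=1e-12)
        for c in classes:
            n_cc = np.sum((ref == c) & (cand == c))
            row = np.sum(ref == c)
            col = np.sum(cand == c)
            assert rep.per_class.loc[c, "specific_agreement"] == pytest.approx(
                2 * n_cc / (row + col), abs=1e-12)
            assert rep.per_class.loc[c, "sensitivity"] == pytest.approx(
                n_cc / row, abs=1e-12)
            assert rep.per_class.loc[c, "specificity"] == pytest.approx(
                (n - row - col + n_cc) / (n - row), abs=1e-12)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(3)
        ref = rng.choice(list(SUBGROUPS), size=100)
        cand = rng.choice(list(SUBGROUPS), size=100)
        perm = dict(zip(SUBGROUPS, np.roll(SUBGROUPS, 2)))
        r1 = t.compare_partitions(ref, cand, classes=SUBGROUPS)
        r2 = t.compare_partitions([perm[x] for x in ref], [perm[x] for x in cand],
                                  classes=SUBGROUPS)
        assert r1.kappa == pytest.approx(r2.kappa, abs=1e-12)
        assert r1.accuracy == pytest.approx(r2.accuracy, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            t.compare_partitions(["a"], ["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            t.compare_partitions([], [])
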