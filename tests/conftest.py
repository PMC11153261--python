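import numpy as np
import pandas as pd
import pytest

import t2dsubgroups as t


@pytest.fixture(scope="session")
def dcs_sim():
    """Realistic-overlap DCS-style cohort (n=400) with ground truth."""
    params = t.default_params("DCS", n_individuals=400, seed=11)
    cohort, truth = t.simulate_cohort(params)
    return cohort, truth.set_index("id")["subgroup"]


@pytest.fixture(scope="session")
def fitted(dcs_sim):
    """Baseline table, named cluster model and labels on the DCS-style cohort."""
    cohort, truth = dcs_sim
    cohort, _ = t.apply_inclusion_criteria(cohort)
    baseline = t.select_baseline(cohort)
    model, idx = t.fit_subgroups(baseline, seed=3)
    model = t.name_clusters(model, t.registry_reference_centres("DCS"))
    labels = t.cluster_labels_named(model, idx)
    entry = baseline.set_index("id")["baseline_duration"]
    return {"cohort": cohort, "baseline": baseline, "model": model,
            "labels": labels, "entry": entry, "truth": truth}


@pytest.fixture(scope="session")
def wellsep():
    """Well-separated mixture (baseline SDs x 0.2): clusters are recoverable."""
    params = t.default_params("DCS", n_individuals=600, seed=5, sd_scale=0.2)
    cohort, truth = t.simulate_cohort(params)
    cohort, _ = t.apply_inclusion_criteria(cohort)
    baseline = t.select_baseline(cohort)
    model, idx = t.fit_subgroups(baseline, seed=1)
    model = t.name_clusters(model, t.registry_reference_centres("DCS"))
    labels = t.cluster_labels_named(model, idx)
    return {"cohort": cohort, "baseline": baseline, "model": model,
            "labels": labels, "truth": truth.set_index("id")["subgroup"]}


@pytest.fixture
def tiny_cohort():
    """Three visits, one individual, one event: smallest useful cohort."""
    individuals = pd.DataFrame({
        "id": ["a"], "sex": ["M"], "age_at_diagnosis": [50.0],
        "gad_positive": [False],
    })
    visits = pd.DataFrame({
        "id": ["a"] * 3,
        "duration": [0.3, 1.5, 0.9],
        "bmi": [28.0, 28.5, 28.2], "hba1c": [55.0, 52.0, 54.0],
        "hdl": [1.1, 1.2, 1.1], "c_peptide": [0.9, np.nan, 0.95],
        "sbp": [140.0, 138.0, 139.0], "dbp": [80.0, 81.0, 80.0],
        "creatinine": [75.0, 76.0, 75.5], "triglycerides": [2.0, 2.1, 2.0],
        "total_chol": [5.0, 5.1, 5.0], "ldl": [3.0, 3.1, 3.0],
        "atc_codes": ["", "A10BA02", ""],
    })
    events = pd.DataFrame({
        "id": ["a"], "outcome": ["AMI"], "time": [4.0], "observed": [True],
    })
    return t.Cohort(individuals, visits, events)
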