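"""Sex-stratified k-means subgrouping of baseline clinical indicators.

Men and women are clustered separately on z-scored indicators and the two
partitions pooled by optimally matching centroids, avoiding sex-dependent
differences in the indicator distributions. Cluster centres are the
arithmetic mean of the scaled vectors of all members (both sexes). Fitted
clusters are named SIDD/SIRD/MOD/MD/MDH by minimum-total-distance assignment
against reference centres (by default the published per-subgroup baseline
mean vectors of the chosen registry).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .constants import INDICATORS, SUBGROUPS

logger = logging.getLogger(__name__)


@dataclass
class ScalingParams:
    """Per-sex, per-indicator location (mean) and scale (sample SD, ddof=1)."""

    location: dict  # sex -> np.ndarray over INDICATORS
    scale: dict

    def transform(self, values: np.ndarray, sex: str) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.location[sex]) / self.scale[sex]

    def inverse(self, z: np.ndarray, sex: str) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.scale[sex] + self.location[sex]


@dataclass
class ClusterModel:
    """Fitted subgrouping model: scaling plus five (optionally named) pooled
    centres in scaled indicator space."""

    scaling: ScalingParams
    centres: np.ndarray           # (5, 5) in scaled space
    names: list | None = None     # bijection onto SUBGROUPS once named
    k: int = 5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=float)
        if self.centres.shape != (self.k, len(INDICATORS)):
            raise ValueError(f"expected {self.k} centres of dim {len(INDICATORS)}")
        if self.names is not None and sorted(self.names) != sorted(SUBGROUPS):
            raise ValueError("names must be a bijection onto the five subgroups")

    @property
    def named(self) -> bool:
        return self.names is not None


def compute_scaling(baseline_table: pd.DataFrame) -> ScalingParams:
    """Per-sex z-score parameters over the five indicators of a baseline
    table (columns ``sex`` and the indicator names)."""
    location, scale = {}, {}
    for sex, grp in baseline_table.groupby("sex"):
        if len(grp) < 2:
            raise ValueError(f"need >= 2 individuals of sex {sex!r} to scale")
        x = grp[list(INDICATORS)].to_numpy(dtype=float)
        loc = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"zero variance for sex {sex!r} in indicator(s) "
                f"{[INDICATORS[i] for i in zero]}"
            )
        location[sex], scale[sex] = loc, sd
    return ScalingParams(location, scale)


def scale_indicators(indicators, sex: str, scaling: ScalingParams) -> np.ndarray:
    """Scale one indicator set to a dimensionless 5-vector in the fixed
    component order (age, bmi, hba1c, c_peptide, hdl)."""
    if isinstance(indicators, (pd.Series, dict)):
        vec = np.array([indicators[k] for k in INDICATORS], dtype=float)
    else:
        vec = np.asarray(indicators, dtype=float)
    if vec.shape != (len(INDICATORS),) or not np.all(np.isfinite(vec)):
        raise ValueError("indicators must be 5 finite values (age, bmi, hba1c, c_peptide, hdl)")
    return scaling.transform(vec, sex)


def _scaled_matrix(table: pd.DataFrame, scaling: ScalingParams) -> np.ndarray:
    out = np.empty((len(table), len(INDICATORS)))
    sexes = table["sex"].to_numpy()
    x = table[list(INDICATORS)].to_numpy(dtype=float)
    for sex in np.unique(sexes):
        sel = sexes == sex
        out[sel] = (x[sel] - scaling.location[sex]) / scaling.scale[sex]
    return out


def fit_subgroups(baseline_table: pd.DataFrame, k: int = 5, seed: int = 0,
                  n_init: int = 25) -> tuple[ClusterModel, pd.Series]:
    """Fit the sex-stratified pooled k-means model.

    Runs k-means separately per sex on the per-sex z-scored indicators,
    matches female to male clusters by optimal one-to-one assignment on
    centroid distance, and defines each pooled centre as the arithmetic mean
    of the scaled vectors of all members of the matched pair.

    Returns the (unnamed) model and per-individual cluster indices aligned
    with ``baseline_table`` (indexed by ``id``).
    """
    scaling = compute_scaling(baseline_table)
    z = _scaled_matrix(baseline_table, scaling)
    sexes = baseline_table["sex"].to_numpy()

    per_sex = {}
    for s_i, sex in enumerate(("M", "F")):
        sel = sexes == sex
        if sel.sum() < k:
            raise ValueError(f"sex stratum {sex!r} has fewer than k={k} individuals")
        for attempt in range(10):
            km = KMeans(n_clusters=k, n_init=n_init, tol=1e-6,
                        random_state=seed + 1000 * s_i + attempt)
            lab = km.fit_predict(z[sel])
            if len(np.unique(lab)) == k:
                break
            logger.warning("empty cluster for sex %s; re-running with new sub-seed", sex)
        else:
            raise RuntimeError(f"k-means kept producing empty clusters for sex {sex!r}")
        per_sex[sex] = (sel, lab, km.cluster_centers_, km.inertia_)

    # match female clusters onto male clusters (optimal assignment)
    cm, cf = per_sex["M"][2], per_sex["F"][2]
    dist = np.linalg.norm(cm[:, None, :] - cf[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(dist)
    f_to_pooled = np.empty(k, dtype=int)
    f_to_pooled[cols] = rows

    cluster_idx = np.empty(len(baseline_table), dtype=int)
    sel_m, lab_m = per_sex["M"][0], per_sex["M"][1]
    sel_f, lab_f = per_sex["F"][0], per_sex["F"][1]
    cluster_idx[sel_m] = lab_m
    cluster_idx[sel_f] = f_to_pooled[lab_f]

    centres = np.vstack([z[cluster_idx == c].mean(axis=0) for c in range(k)])
    counts = np.bincount(cluster_idx, minlength=k)
    model = ClusterModel(
        scaling=scaling, centres=centres, k=k,
        metadata={"seed": seed, "n_init": n_init,
                  "n_per_cluster": counts.tolist(),
                  "inertia": {s: float(per_sex[s][3]) for s in per_sex},
                  "cross_sex_match_distance": float(dist[rows, cols].sum())},
    )
    labels = pd.Series(cluster_idx, index=baseline_table["id"].to_numpy(), name="cluster")
    return model, labels


def reference_centres_scaled(raw_centres: pd.DataFrame, scaling: ScalingParams) -> np.ndarray:
    """Scale raw-unit reference centres (rows indexed by subgroup name,
    columns = indicators) into the model's pooled scaled space.

    Each raw vector is scaled with each sex's parameters and the two scaled
    vectors averaged, mirroring how pooled centres average both sexes.
    """
    x = raw_centres[list(INDICATORS)].to_numpy(dtype=float)
    zs = [
        (x - scaling.location[sex]) / scaling.scale[sex]
        for sex in scaling.location
    ]
    return np.mean(zs, axis=0)


def name_clusters(model: ClusterModel, reference_centres,
                  reference_names=SUBGROUPS) -> ClusterModel:
    """Name fitted centres by minimum-total-Euclidean-distance one-to-one
    assignment against the five named reference centres.

    ``reference_centres`` is either an array already in scaled space (rows
    ordered as ``reference_names``) or a DataFrame of raw-unit vectors
    indexed by subgroup name (scaled with the model's own ScalingParams).
    """
    if isinstance(reference_centres, pd.DataFrame):
        reference_names = list(reference_centres.index)
        ref = reference_centres_scaled(reference_centres, model.scaling)
    else:
        ref = np.asarray(reference_centres, dtype=float)
        reference_names = list(reference_names)
    if ref.shape != (model.k, len(INDICATORS)) or len(reference_names) != model.k:
        raise ValueError(f"expected exactly {model.k} reference centres with names")
    dist = np.linalg.norm(model.centres[:, None, :] - ref[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(dist)
    names = [None] * model.k
    for r, c in zip(rows, cols):
        names[r] = reference_names[c]
    return ClusterModel(
        scaling=model.scaling, centres=model.centres, names=names, k=model.k,
        metadata={**model.metadata,
                  "naming_distance_matrix": dist.tolist(),
                  "naming_total_distance": float(dist[rows, cols].sum())},
    )


def assign_nearest_centre(indicators, sex: str, model: ClusterModel) -> str:
    """Assign one indicator set to the named centre at minimum Euclidean
    distance in scaled space; ties break by the fixed subgroup order."""
    if not model.named:
        raise ValueError("model must be named before assignment")
    z = scale_indicators(indicators, sex, model.scaling)
    d = np.linalg.norm(model.centres - z, axis=1)
    order = np.array([SUBGROUPS.index(nm) for nm in model.names])
    tied = np.flatnonzero(d == d.min())
    best = tied[np.argmin(order[tied])]  # canonical name order breaks exact ties
    return model.names[best]


def assign_table(table: pd.DataFrame, model: ClusterModel) -> pd.Series:
    """Vectorised nearest-centre assignment for a baseline-like table
    (columns ``id``, ``sex`` and the five indicators)."""
    if not model.named:
        raise ValueError("model must be named before assignment")
    z = _scaled_matrix(table, model.scaling)
    d = np.linalg.norm(z[:, None, :] - model.centres[None, :, :], axis=2)
    order = np.array([SUBGROUPS.index(nm) for nm in model.names])
    # distance-then-canonical-name-order tie-break, applied exactly
    masked = np.where(d == d.min(axis=1, keepdims=True), order, np.inf)
    best = np.argmin(masked, axis=1)
    labels = [model.names[b] for b in best]
    return pd.Series(labels, index=table["id"].to_numpy(), name="subgroup")


def cluster_labels_named(model: ClusterModel, cluster_idx: pd.Series) -> pd.Series:
    """Translate fitted cluster indices into subgroup names."""
    if not model.named:
        raise ValueError("model must be named first")
    return cluster_idx.map(lambda c: model.names[int(c)]).rename("subgroup")


def save_model(model: ClusterModel, path) -> None:
    """Serialise a fitted model (scaling, centres, names, metadata) to a
    YAML document."""
    import yaml
    doc = {
        "k": model.k,
        "scaling": {
            "location": {s: v.tolist() for s, v in model.scaling.location.items()},
            "scale": {s: v.tolist() for s, v in model.scaling.scale.items()},
        },
        "centres": model.centres.tolist(),
        "names": list(model.names) if model.names else None,
        "metadata": model.metadata,
        "indicator_order": list(INDICATORS),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> ClusterModel:
    """Inverse of :func:`save_model`."""
    import yaml
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    scaling = ScalingParams(
        location={s: np.asarray(v, dtype=float)
                  for s, v in doc["scaling"]["location"].items()},
        scale={s: np.asarray(v, dtype=float)
               for s, v in doc["scaling"]["scale"].items()},
    )
    return ClusterModel(scaling=scaling, centres=np.asarray(doc["centres"]),
                        names=doc["names"], k=doc["k"],
                        metadata=doc.get("metadata", {}))


def registry_reference_centres(cohort_style: str = "DCS") -> pd.DataFrame:
    """Published per-subgroup baseline indicator means (raw units) of the
    chosen registry, for naming fitted clusters."""
    from .simulate import _TABLE_DCS, _TABLE_GODARTS
    if cohort_style not in ("DCS", "GoDARTS"):
        raise ValueError(f"unknown cohort style: {cohort_style!r}")
    table = _TABLE_DCS if cohort_style == "DCS" else _TABLE_GODARTS
    rows = {name: {k: table[name][k][0] for k in INDICATORS} for name in SUBGROUPS}
    return pd.DataFrame.from_dict(rows, orient="index")[list(INDICATORS)]
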