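"""Longitudinal consistency of subgroup membership.

Subgroup membership is re-assessed in half-open follow-up windows (default
[0,2), [2,4), [4,6), [6,8) years of diabetes duration) by two algorithms:

* de novo re-clustering — re-scale within the window, re-fit the
  sex-stratified k-means, and name the shifted centres against the baseline
  model's centres;
* centre-based reallocation — assign each windowed observation to the
  nearest baseline centre under the frozen baseline scaling.

Agreement against baseline labels, transition trajectories across windows
and the severe/mild movement dichotomy are derived from the per-window
labels.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .agreement import AgreementReport, compare_partitions
from .cohort import Cohort
from .constants import INDICATORS, MILD_SUBGROUPS, SEVERE_SUBGROUPS, SUBGROUPS
from .subgrouping import (ClusterModel, assign_table, cluster_labels_named,
                          fit_subgroups, name_clusters)

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS = ((0.0, 2.0), (2.0, 4.0), (4.0, 6.0), (6.0, 8.0))


@dataclass
class WindowSpec:
    """Ordered non-overlapping half-open duration intervals [a, b)."""

    windows: tuple = DEFAULT_WINDOWS

    def __post_init__(self) -> None:
        w = tuple(tuple(map(float, x)) for x in self.windows)
        for a, b in w:
            if not a < b:
                raise ValueError(f"degenerate window [{a}, {b})")
        for (a1, b1), (a2, b2) in zip(w, w[1:]):
            if a2 < b1:
                raise ValueError("windows must be non-overlapping and increasing")
        self.windows = w

    def label(self, i: int) -> str:
        a, b = self.windows[i]
        return f"[{a:g},{b:g})"

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class TransitionTable:
    trajectories: pd.DataFrame    # one row per distinct label sequence, with count
    top: pd.DataFrame             # top-N by count (ties lexicographic)
    stay_fraction: pd.Series      # per starting subgroup
    n_complete: int


def window_indicators(cohort: Cohort, windows: WindowSpec,
                      baseline_table: pd.DataFrame,
                      carry_forward_c_peptide: bool = True) -> pd.DataFrame:
    """Windowed clustering indicators per (individual, window).

    bmi/hba1c/hdl are within-window means of available values; C-peptide is
    carried forward from baseline (no follow-up C-peptide is assumed; set
    ``carry_forward_c_peptide=False`` to use measured in-window means when
    present); age is the age at the first in-window visit. Individuals
    lacking any required component in a window are dropped from that window.

    Returns a long table: ``window, id, sex, age, bmi, hba1c, c_peptide, hdl``.
    """
    base = baseline_table.set_index("id")
    visits = cohort.visits.merge(
        cohort.individuals[["id", "sex", "age_at_diagnosis"]], on="id")
    frames = []
    for i, (a, b) in enumerate(windows.windows):
        inw = visits[(visits["duration"] >= a) & (visits["duration"] < b)]
        if inw.empty:
            continue
        agg = inw.groupby("id").agg(
            bmi=("bmi", "mean"), hba1c=("hba1c", "mean"), hdl=("hdl", "mean"),
            cpep_measured=("c_peptide", "mean"),
            first_duration=("duration", "min"),
            age_at_diagnosis=("age_at_diagnosis", "first"),
            sex=("sex", "first"),
        ).reset_index()
        agg = agg[agg["id"].isin(base.index)]
        agg["age"] = agg["age_at_diagnosis"] + agg["first_duration"]
        cpep_base = agg["id"].map(base["c_peptide"])
        if carry_forward_c_peptide:
            agg["c_peptide"] = cpep_base
        else:
            agg["c_peptide"] = agg["cpep_measured"].fillna(cpep_base)
        agg["window"] = windows.label(i)
        out = agg[["window", "id", "sex", *INDICATORS]]
        complete = out[list(INDICATORS)].notna().all(axis=1)
        n_drop = int((~complete).sum())
        if n_drop:
            logger.info("window %s: dropped %d individual(s) with incomplete indicators",
                        windows.label(i), n_drop)
        frames.append(out[complete])
    if not frames:
        return pd.DataFrame(columns=["window", "id", "sex", *INDICATORS])
    return pd.concat(frames, ignore_index=True)


def denovo_reallocate(window_table: pd.DataFrame, baseline_model: ClusterModel,
                      seed: int = 0) -> tuple[dict, dict]:
    """De novo re-clustering per window.

    Each window is re-scaled and re-clustered from scratch; the shifted
    centres are named against the baseline model's centres by optimal
    assignment. Windows too small to cluster are skipped with a warning.

    Returns (labels, shifted_centres): labels maps window label to a Series
    of subgroup names indexed by id; shifted_centres maps window label to
    the named ClusterModel of that window.
    """
    if not baseline_model.named:
        raise ValueError("baseline model must be named")
    labels, centres = {}, {}
    for w, tbl in window_table.groupby("window", sort=False):
        try:
            model, idx = fit_subgroups(tbl.reset_index(drop=True), k=baseline_model.k,
                                       seed=seed)
        except ValueError as exc:
            logger.warning("window %s skipped for de novo clustering: %s", w, exc)
            continue
        named = name_clusters(model, baseline_model.centres,
                              reference_names=baseline_model.names)
        labels[w] = cluster_labels_named(named, idx)
        centres[w] = named
    return labels, centres


def centre_reallocate(window_table: pd.DataFrame,
                      baseline_model: ClusterModel) -> dict:
    """Centre-based reallocation: nearest baseline centre under the frozen
    baseline scaling, per window. Deterministic; no re-fitting."""
    return {w: assign_table(tbl, baseline_model)
            for w, tbl in window_table.groupby("window", sort=False)}


def consistency_report(baseline_labels: pd.Series,
                       window_labels: dict) -> tuple[dict, float]:
    """Per-window agreement against baseline labels plus the relative
    accuracy change between first and last window.

    ``baseline_labels`` is indexed by id; each entry of ``window_labels``
    likewise. Agreement in each window uses the individuals present in both.
    """
    reports: dict[str, AgreementReport] = {}
    for w, lab in window_labels.items():
        common = lab.index.intersection(baseline_labels.index)
        if len(common) == 0:
            raise ValueError(f"window {w} shares no individuals with baseline")
        reports[w] = compare_partitions(baseline_labels.loc[common], lab.loc[common],
                                        classes=SUBGROUPS)
    accs = [r.accuracy for r in reports.values()]
    trend = (accs[-1] - accs[0]) / accs[0] if accs and accs[0] > 0 else 0.0
    return reports, float(trend)


def enumerate_transitions(window_labels: dict, top_n: int = 10) -> TransitionTable:
    """Trajectory counts over individuals observed in every window.

    A trajectory is the tuple of subgroup labels across windows in order.
    The top-N ranking breaks count ties lexicographically; the per-subgroup
    stay fraction is the fraction of complete-sequence individuals starting
    in a subgroup whose whole sequence is constant.
    """
    if not window_labels:
        raise ValueError("no window labels given")
    wins = list(window_labels)
    frame = pd.DataFrame({w: window_labels[w] for w in wins}).dropna()
    if frame.empty:
        raise ValueError("no individual has labels in every window")
    seqs = [tuple(row) for row in frame.to_numpy()]
    counts = Counter(seqs)
    traj = pd.DataFrame(
        [{"trajectory": " -> ".join(s), "count": c,
          **{w: s[i] for i, w in enumerate(wins)}}
         for s, c in counts.items()]
    ).sort_values(["count", "trajectory"], ascending=[False, True],
                  kind="stable").reset_index(drop=True)
    top = traj.head(top_n).reset_index(drop=True)

    start = frame.iloc[:, 0]
    stayed = frame.apply(lambda r: len(set(r)) == 1, axis=1)
    stay = stayed.groupby(start).mean().reindex(SUBGROUPS)
    stay.name = "stay_fraction"
    return TransitionTable(traj, top, stay, n_complete=len(frame))


_MOVE = {True: "severe", False: "mild"}


def severe_mild_movement(baseline_labels: pd.Series,
                         window_labels: pd.Series) -> pd.Series:
    """Classify each individual's movement between the severe (SIDD, SIRD)
    and mild (MOD, MD, MDH) subgroup families from baseline to a follow-up
    window, as 'severe->severe', 'severe->mild', 'mild->severe' or
    'mild->mild'."""
    common = baseline_labels.index.intersection(window_labels.index)
    out = {}
    for i in common:
        a, b = baseline_labels.loc[i], window_labels.loc[i]
        for lab in (a, b):
            if lab not in SEVERE_SUBGROUPS and lab not in MILD_SUBGROUPS:
                raise ValueError(f"unknown subgroup label: {lab!r}")
        out[i] = f"{_MOVE[a in SEVERE_SUBGROUPS]}->{_MOVE[b in SEVERE_SUBGROUPS]}"
    return pd.Series(out, name="movement")
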