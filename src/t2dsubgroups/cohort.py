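"""Registry-style longitudinal cohort container, I/O and baseline selection.

A :class:`Cohort` holds three tables on a diabetes-duration time axis
(fractional years, 0 at diagnosis; windows are half-open ``[a, b)``):

* ``individuals`` — one row per person: ``id, sex, age_at_diagnosis,
  gad_positive``;
* ``visits`` — one row per clinical observation: ``id, duration``, ten
  measurement columns and a semicolon-joined ``atc_codes`` field;
* ``events`` — first diabetes-related complications per person and outcome:
  ``id, outcome, time, observed``.

Missing measurements are NaN in memory and empty cells on disk, never coded
numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import INDICATORS, MEASUREMENTS, OUTCOMES

logger = logging.getLogger(__name__)

INDIVIDUAL_COLUMNS = ["id", "sex", "age_at_diagnosis", "gad_positive"]
VISIT_COLUMNS = ["id", "duration", *MEASUREMENTS, "atc_codes"]
EVENT_COLUMNS = ["id", "outcome", "time", "observed"]

#: visit columns holding the five clustering indicators (age is derived)
BASELINE_INDICATOR_COLUMNS = ["bmi", "hba1c", "hdl", "c_peptide"]


class SchemaError(ValueError):
    """A table is missing a mandatory column."""


class CohortValidationError(ValueError):
    """A cohort invariant is violated."""


@dataclass
class Cohort:
    """Validated longitudinal cohort.

    Parameters
    ----------
    individuals, visits, events
        Tables with the column schemas above.
    metadata
        Free-form provenance (name, time-axis convention, simulation seed).
    """

    individuals: pd.DataFrame
    visits: pd.DataFrame
    events: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.individuals = self.individuals.reset_index(drop=True)
        self.visits = self.visits.reset_index(drop=True)
        self.events = self.events.reset_index(drop=True)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        for name, df, cols in (
            ("individuals", self.individuals, INDIVIDUAL_COLUMNS),
            ("visits", self.visits, VISIT_COLUMNS),
            ("events", self.events, EVENT_COLUMNS),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"{name} table missing column(s): {missing}")

        ind = self.individuals
        if ind["id"].duplicated().any():
            dup = ind.loc[ind["id"].duplicated(), "id"].tolist()
            raise CohortValidationError(f"duplicate individual id(s): {dup}")
        if not ind["sex"].isin(["M", "F"]).all():
            raise CohortValidationError("sex must be 'M' or 'F'")
        if (ind["age_at_diagnosis"] <= 0).any():
            raise CohortValidationError("age_at_diagnosis must be > 0")

        known = set(ind["id"])
        for name, df in (("visits", self.visits), ("events", self.events)):
            unknown = set(df["id"]) - known
            if unknown:
                raise CohortValidationError(
                    f"{name} reference unknown individual(s): {sorted(unknown)[:5]}"
                )

        dur = pd.to_numeric(self.visits["duration"], errors="coerce")
        if dur.isna().any() or (dur < 0).any() or np.isinf(dur).any():
            raise CohortValidationError("visit duration must be finite and >= 0")
        for m in MEASUREMENTS:
            vals = self.visits[m]
            if (vals.dropna() <= 0).any():
                raise CohortValidationError(f"measurement '{m}' must be > 0 when present")

        ev = self.events
        if len(ev):
            if not ev["outcome"].isin(OUTCOMES).all():
                bad = sorted(set(ev["outcome"]) - set(OUTCOMES))
                raise CohortValidationError(f"unknown outcome label(s): {bad}")
            if (ev["time"] <= 0).any():
                raise CohortValidationError("event time must be > 0")
            dups = ev.duplicated(subset=["id", "outcome"])
            if dups.any():
                pairs = ev.loc[dups, ["id", "outcome"]].values.tolist()
                raise CohortValidationError(
                    f"duplicate (individual, outcome) event record(s): {pairs[:5]}"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def visits_of(self, individual_id) -> pd.DataFrame:
        v = self.visits[self.visits["id"] == individual_id]
        return v.sort_values("duration", kind="stable")


# -- I/O -------------------------------------------------------------------

def _read_table(path, required, numeric):
    df = pd.read_csv(path, dtype={"id": str, "atc_codes": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{Path(path).name} missing column(s): {missing}")
    n_bad = 0
    for c in numeric:
        raw = df[c]
        coerced = pd.to_numeric(raw, errors="coerce")
        n_bad += int((coerced.isna() & raw.notna()).sum())
        df[c] = coerced
    if n_bad:
        logger.warning("%s: %d unparseable cell(s) treated as missing", path, n_bad)
    return df


def read_cohort(visits_path, events_path, individuals_path, name: str = "") -> Cohort:
    """Read the three comma-delimited schema tables into a validated Cohort."""
    individuals = _read_table(individuals_path, INDIVIDUAL_COLUMNS, ["age_at_diagnosis"])
    individuals["gad_positive"] = individuals["gad_positive"].astype(int).astype(bool)
    visits = _read_table(visits_path, VISIT_COLUMNS, ["duration", *MEASUREMENTS])
    visits["atc_codes"] = visits["atc_codes"].fillna("")
    events = _read_table(events_path, EVENT_COLUMNS, ["time"])
    if len(events):
        events["observed"] = events["observed"].astype(int).astype(bool)
    else:
        events["observed"] = events["observed"].astype(bool)
    meta = {"name": name or Path(individuals_path).parent.name, "time_axis": "duration_years"}
    return Cohort(individuals, visits, events, metadata=meta)


def write_cohort(cohort: Cohort, directory) -> dict:
    """Write the three schema tables; inverse of :func:`read_cohort`.

    Returns a mapping of table name to path. Missing measurements become
    empty cells.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "individuals": directory / "individuals.csv",
        "visits": directory / "visits.csv",
        "events": directory / "events.csv",
    }
    ind = cohort.individuals.copy()
    ind["gad_positive"] = ind["gad_positive"].astype(int)
    ind[INDIVIDUAL_COLUMNS].to_csv(paths["individuals"], index=False)
    cohort.visits[VISIT_COLUMNS].to_csv(paths["visits"], index=False)
    ev = cohort.events.copy()
    if len(ev):
        ev["observed"] = ev["observed"].astype(int)
    ev[EVENT_COLUMNS].to_csv(paths["events"], index=False)
    return paths


# -- inclusion and baseline -----------------------------------------------

def _complete_indicator_mask(visits: pd.DataFrame) -> pd.Series:
    return visits[BASELINE_INDICATOR_COLUMNS].notna().all(axis=1)


def apply_inclusion_criteria(
    cohort: Cohort,
    max_baseline_duration: float = 2.0,
    min_diagnosis_age: float = 35.0,
    missing_gad_as_negative: bool = False,
) -> tuple[Cohort, dict]:
    """Apply the study inclusion filter.

    Retains individuals with diagnosis age >= ``min_diagnosis_age``, GAD
    negativity and at least one visit within ``max_baseline_duration`` years
    of diagnosis carrying all five clustering indicators. Missing GAD status
    excludes unless ``missing_gad_as_negative``.

    Returns the filtered cohort and per-criterion exclusion counts (an
    individual is counted once, at the first failed criterion in the order
    age, GAD, indicators).
    """
    ind = cohort.individuals
    age_ok = ind["age_at_diagnosis"] >= min_diagnosis_age
    gad = ind["gad_positive"]
    if missing_gad_as_negative:
        gad_ok = ~gad.fillna(False).astype(bool)
    else:
        gad_ok = gad.notna() & ~gad.astype(bool)

    v = cohort.visits
    qualifying = v[(v["duration"] <= max_baseline_duration) & _complete_indicator_mask(v)]
    has_baseline = ind["id"].isin(qualifying["id"]).to_numpy()

    exclusions = {
        "age": int((~age_ok).sum()),
        "gad": int((age_ok & ~gad_ok).sum()),
        "indicators": int((age_ok & gad_ok & ~has_baseline).sum()),
    }
    keep = age_ok & gad_ok & has_baseline
    kept_ids = set(ind.loc[keep, "id"])
    filtered = Cohort(
        ind[keep],
        cohort.visits[cohort.visits["id"].isin(kept_ids)],
        cohort.events[cohort.events["id"].isin(kept_ids)],
        metadata={**cohort.metadata, "inclusion_applied": True},
    )
    return filtered, exclusions


def select_baseline(cohort: Cohort, max_baseline_duration: float = 2.0) -> pd.DataFrame:
    """Pick each individual's baseline: the complete-indicator visit nearest
    diagnosis.

    Returns a table with one row per individual: ``id, sex, baseline_duration``
    and the five clustering indicators, where ``age`` is the age at the
    baseline observation (age at diagnosis plus baseline duration). Ties on
    duration keep the first visit in input order (logged).
    """
    v = cohort.visits
    ok = v[(v["duration"] <= max_baseline_duration) & _complete_indicator_mask(v)]
    if ok.empty:
        return pd.DataFrame(columns=["id", "sex", "baseline_duration", *INDICATORS])
    idx = ok.groupby("id", sort=False)["duration"].idxmin()
    base = ok.loc[idx]
    n_ties = int(
        ok.merge(base[["id", "duration"]], on=["id", "duration"]).groupby("id").size().gt(1).sum()
    )
    if n_ties:
        logger.warning("%d individual(s) had tied baseline durations; kept first in input order", n_ties)
    base = base.merge(cohort.individuals[["id", "sex", "age_at_diagnosis"]], on="id")
    base["age"] = base["age_at_diagnosis"] + base["duration"]
    base = base.rename(columns={"duration": "baseline_duration"})
    dropped = set(cohort.individuals["id"]) - set(base["id"])
    if dropped:
        logger.warning("%d individual(s) lack a qualifying baseline visit: %s",
                       len(dropped), sorted(dropped)[:5])
    out = base[["id", "sex", "baseline_duration", *INDICATORS]].reset_index(drop=True)
    return out
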