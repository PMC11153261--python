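"""ATC-code treatment-step classification and medication-pattern models.

Treatment intensity is a mutually exclusive six-level category derived from
the drugs active at an observation: no treatment (diet and exercise), only
CVD treatment (ATC C01-C10), step 1 (metformin A10BA02 or the glinides
A10BX), step 2 (adding sulfonylurea A10BB), step 3 (adding insulin A10A)
and other OAD (DPP-4 inhibitors A10BH, GLP-1 analogues A10BJ,
alpha-glucosidase inhibitors A10BF, SGLT2 inhibitors A10BK,
thiazolidinediones A10BG, liraglutide A10BX07, dapagliflozin A10BX09).

The "adding" language defines a cumulative ladder: the assigned step is the
highest rung present, with precedence Step3 > Step2 > Step1 > OtherOAD >
OnlyCVD > NoTreatment (an alternative precedence placing OtherOAD above the
ladder is selectable). Liraglutide and dapagliflozin are carved out of the
generic A10BX glinide rule.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort
from .constants import INDICATORS, SUBGROUPS, TREATMENT_STEPS

logger = logging.getLogger(__name__)

_OTHER_OAD_PREFIXES = ("A10BH", "A10BJ", "A10BF", "A10BK", "A10BG")
_OTHER_OAD_SPECIFIC = ("A10BX07", "A10BX09")
_CVD_PREFIXES = tuple(f"C{i:02d}" for i in range(1, 11))
_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{0,2}\d{0,2}$")

PRECEDENCE_LADDER_FIRST = ("Step3", "Step2", "Step1", "OtherOAD", "OnlyCVD")
PRECEDENCE_OTHER_FIRST = ("Step3", "OtherOAD", "Step2", "Step1", "OnlyCVD")


def _code_classes(codes) -> set:
    found = set()
    for raw in codes:
        code = str(raw).strip().upper()
        if not code:
            continue
        if not _ATC_RE.match(code):
            logger.warning("ignoring malformed ATC code: %r", raw)
            continue
        if code.startswith("A10A"):
            found.add("Step3")
        elif code.startswith("A10BB"):
            found.add("Step2")
        elif code in _OTHER_OAD_SPECIFIC or code.startswith(_OTHER_OAD_PREFIXES):
            found.add("OtherOAD")
        elif code == "A10BA02" or code.startswith("A10BX"):
            found.add("Step1")
        elif code.startswith(_CVD_PREFIXES):
            found.add("OnlyCVD")
    return found


def classify_treatment_step(atc_codes, precedence=PRECEDENCE_LADDER_FIRST) -> str:
    """Classify a set of active ATC codes into one treatment step."""
    found = _code_classes(atc_codes)
    for step in precedence:
        if step in found:
            return step
    return "NoTreatment"


def step_per_interval(cohort: Cohort,
                      precedence=PRECEDENCE_LADDER_FIRST) -> pd.DataFrame:
    """Treatment step per (individual, integer duration year).

    The step for year bin [y, y+1) is classified from the earliest visit in
    the bin; bins without visits are absent (no carry-forward, censoring
    ignored). Returns columns ``id, year, step``.
    """
    v = cohort.visits[["id", "duration", "atc_codes"]].copy()
    v["year"] = np.floor(v["duration"]).astype(int)
    first = v.sort_values("duration", kind="stable").groupby(["id", "year"], sort=False).first()
    first = first.reset_index()
    first["step"] = [
        classify_treatment_step(str(c).split(";") if pd.notna(c) and str(c) else [],
                                precedence=precedence)
        for c in first["atc_codes"]
    ]
    out = first[["id", "year", "step"]].sort_values(["id", "year"]).reset_index(drop=True)
    return out


def step_area_summary(step_table: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Proportion of individuals in each step per (subgroup, year) — the
    area-graph table. Proportions are exact rational counts and sum to 1
    within every non-empty cell."""
    t = step_table[step_table["id"].isin(labels.index)].copy()
    t["subgroup"] = t["id"].map(labels)
    counts = (t.groupby(["subgroup", "year", "step"]).size()
              .rename("count").reset_index())
    totals = counts.groupby(["subgroup", "year"])["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts


@dataclass
class MultinomialResult:
    coefficients: pd.DataFrame   # long: category, term, coef, se
    rrr: pd.DataFrame            # relative-risk ratios with 95% CI
    reference_category: str
    reference_subgroup: str
    loglik: float
    aic: float
    n: int


def _step_design(step_table: pd.DataFrame, predictors: str, labels: pd.Series,
                 baseline_table: pd.DataFrame | None, individuals: pd.DataFrame,
                 reference_subgroup: str) -> tuple[pd.DataFrame, pd.Series]:
    t = step_table[step_table["id"].isin(labels.index)].copy()
    t = t.merge(individuals[["id", "sex"]], on="id")
    X = pd.DataFrame({"const": 1.0, "duration": t["year"].astype(float)},
                     index=t.index)
    X["sex_M"] = (t["sex"] == "M").astype(float)
    if predictors in ("subgroups", "both"):
        sub = t["id"].map(labels)
        for s in SUBGROUPS:
            if s == reference_subgroup:
                continue
            X[f"subgroup_{s}"] = (sub == s).astype(float)
    if predictors in ("indicators", "both"):
        if baseline_table is None:
            raise ValueError("baseline_table required for indicator predictors")
        base = baseline_table.set_index("id")
        for k in INDICATORS:
            X[f"baseline_{k}"] = t["id"].map(base[k]).to_numpy()
    keep = X.notna().all(axis=1)
    X, steps = X[keep], t.loc[keep, "step"]
    constant = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
    if constant:
        logger.warning("dropping constant covariate(s): %s", constant)
        X = X.drop(columns=constant)
    return X, steps


def fit_multinomial(step_table: pd.DataFrame, predictors: str, labels: pd.Series,
                    individuals: pd.DataFrame,
                    baseline_table: pd.DataFrame | None = None,
                    reference_subgroup: str = "MD") -> MultinomialResult:
    """Multinomial logit of treatment step on the chosen predictor set.

    Person-year observations from ``step_per_interval`` are the units;
    NoTreatment is the reference outcome category and ``reference_subgroup``
    the reference subgroup contrast, so the Step3-vs-NoTreatment SIDD
    coefficient is the insulin relative-risk contrast of interest.
    Empty outcome categories are dropped with a warning.
    """
    if predictors not in ("subgroups", "indicators", "both"):
        raise ValueError("predictors must be 'subgroups', 'indicators' or 'both'")
    X, steps = _step_design(step_table, predictors, labels, baseline_table,
                            individuals, reference_subgroup)
    present = [s for s in TREATMENT_STEPS if s in set(steps)]
    missing = [s for s in TREATMENT_STEPS if s not in present]
    if missing:
        logger.warning("empty treatment-step category(ies) dropped: %s", missing)
    if len(present) < 2:
        raise ValueError("need at least two observed treatment-step categories")
    cat = pd.Categorical(steps, categories=present, ordered=False)
    endog = pd.Series(cat.codes, index=steps.index)

    model = sm.MNLogit(endog.to_numpy(), X.to_numpy())
    res = None
    # newton can overflow to a nan log-likelihood on sparse categories
    for method in ("newton", "bfgs", "lbfgs"):
        try:
            cand = model.fit(method=method, maxiter=500, disp=False)
        except np.linalg.LinAlgError:
            continue
        if cand.mle_retvals.get("converged", True) and np.isfinite(cand.llf):
            res = cand
            break
    if res is None:
        raise RuntimeError("multinomial fit did not converge (possible separation)")

    terms = list(X.columns)
    cats = present[1:]  # category 0 (NoTreatment when present) is reference
    coef_rows = []
    for j, catname in enumerate(cats):
        for i, term in enumerate(terms):
            b = float(res.params[i, j])
            se = float(res.bse[i, j])
            coef_rows.append({
                "category": catname, "term": term, "coef": b, "se": se,
                "rrr": float(np.exp(b)),
                "rrr_lower95": float(np.exp(b - 1.959963984540054 * se)),
                "rrr_upper95": float(np.exp(b + 1.959963984540054 * se)),
            })
    coefs = pd.DataFrame(coef_rows)
    rrr = coefs[["category", "term", "rrr", "rrr_lower95", "rrr_upper95"]]
    k_params = res.params.size
    loglik = float(res.llf)
    return MultinomialResult(
        coefficients=coefs[["category", "term", "coef", "se"]],
        rrr=rrr,
        reference_category=present[0],
        reference_subgroup=reference_subgroup,
        loglik=loglik,
        aic=float(2 * k_params - 2 * loglik),
        n=int(len(endog)),
    )
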