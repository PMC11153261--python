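"""Risk-factor trajectories by subgroup.

Annual descriptive summaries (mean ± SD per integer duration-year bin) and
linear random-intercept models

    value_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, s_b^2),  e_ij ~ N(0, s_e^2)

fitted by maximum likelihood (not REML), so AICs are comparable across
fixed-effect structures. Fixed effects: diabetes duration, sex and either
discrete subgroup membership (four contrasts vs a reference subgroup),
the five baseline clustering indicators, or both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort
from .constants import INDICATORS, SUBGROUPS, TRAJECTORY_PARAMETERS

PREDICTOR_SETS = ("subgroups", "indicators", "both")


@dataclass
class MixedModelResult:
    params: pd.Series            # fixed-effect estimates
    bse: pd.Series               # their standard errors
    random_intercept_var: float
    residual_var: float
    loglik: float
    aic: float
    n_obs: int
    n_individuals: int
    converged: bool


def annual_summary(cohort: Cohort, parameter: str, labels: pd.Series) -> pd.DataFrame:
    """Per (subgroup, integer duration-year) n / mean / SD of a clinical
    parameter; missing values omitted. SD for singleton bins is reported as
    0 with ``sd_degenerate=True``."""
    if parameter not in TRAJECTORY_PARAMETERS:
        raise ValueError(f"unknown trajectory parameter: {parameter!r}")
    v = cohort.visits[["id", "duration", parameter]].dropna(subset=[parameter])
    v = v[v["id"].isin(labels.index)].copy()
    v["subgroup"] = v["id"].map(labels)
    v["year"] = np.floor(v["duration"]).astype(int)
    g = v.groupby(["subgroup", "year"])[parameter]
    out = g.agg(n="size", mean="mean", sd=lambda x: x.std(ddof=1)).reset_index()
    out["sd_degenerate"] = out["n"] == 1
    out.loc[out["sd_degenerate"], "sd"] = 0.0
    out["parameter"] = parameter
    return out


def _fixed_effects_design(cohort: Cohort, parameter: str, predictors: str,
                          labels: pd.Series, baseline_table: pd.DataFrame | None,
                          reference_subgroup: str) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    if predictors not in PREDICTOR_SETS:
        raise ValueError(f"predictors must be one of {PREDICTOR_SETS}")
    v = cohort.visits[["id", "duration", parameter]].dropna(subset=[parameter])
    v = v[v["id"].isin(labels.index)]
    v = v.merge(cohort.individuals[["id", "sex"]], on="id")
    X = pd.DataFrame({"const": 1.0, "duration": v["duration"].to_numpy()},
                     index=v.index)
    X["sex_M"] = (v["sex"] == "M").astype(float)
    if predictors in ("subgroups", "both"):
        sub = v["id"].map(labels)
        for s in SUBGROUPS:
            if s == reference_subgroup:
                continue
            X[f"subgroup_{s}"] = (sub == s).astype(float)
    if predictors in ("indicators", "both"):
        if baseline_table is None:
            raise ValueError("baseline_table required for indicator predictors")
        base = baseline_table.set_index("id")
        for k in INDICATORS:
            X[f"baseline_{k}"] = v["id"].map(base[k]).to_numpy()
        keep = X.notna().all(axis=1)
        X, v = X[keep], v[keep]
    return X, v[parameter], v["id"]


def fit_random_intercept(cohort: Cohort, parameter: str, predictors: str,
                         labels: pd.Series,
                         baseline_table: pd.DataFrame | None = None,
                         reference_subgroup: str = "SIDD") -> MixedModelResult:
    """ML fit of the random-intercept model for one clinical parameter.

    ``labels`` is a Series of subgroup names indexed by individual id;
    ``predictors`` selects the fixed-effect set. AIC counts fixed effects
    plus the two variance parameters.
    """
    if parameter not in TRAJECTORY_PARAMETERS:
        raise ValueError(f"unknown trajectory parameter: {parameter!r}")
    X, y, groups = _fixed_effects_design(cohort, parameter, predictors, labels,
                                         baseline_table, reference_subgroup)
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few observations to fit the mixed model")
    model = sm.MixedLM(endog=np.asarray(y, dtype=float), exog=X,
                       groups=np.asarray(groups))
    res, last_exc = None, None
    for method in ("lbfgs", "cg", "powell"):  # lbfgs can hit singular Hessians
        try:
            res = model.fit(reml=False, method=method, maxiter=500, disp=False)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
            continue
        if res.converged:
            break
    if res is None:
        raise RuntimeError(f"mixed model for {parameter!r} failed: {last_exc}")
    if not res.converged:
        raise RuntimeError(f"mixed model for {parameter!r} did not converge")
    k_fe = X.shape[1]
    loglik = float(res.llf)
    aic = 2 * (k_fe + 2) - 2 * loglik
    return MixedModelResult(
        params=res.fe_params,
        bse=res.bse_fe,
        random_intercept_var=float(np.asarray(res.cov_re).ravel()[0]),
        residual_var=float(res.scale),
        loglik=loglik,
        aic=aic,
        n_obs=int(len(y)),
        n_individuals=int(pd.Series(groups).nunique()),
        converged=bool(res.converged),
    )
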