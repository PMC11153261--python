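"""Predictor-set comparison via AIC and relative likelihood.

Each model target (a risk-factor trajectory, an outcome's Cox model, the
treatment multinomial) is fitted three times on identical data with fixed
effects drawn from {baseline indicators, discrete subgroups, both}. Models
are compared per target by AIC; the evidence for model i relative to the
per-target AIC minimiser is the relative likelihood

    RL_i = exp((AIC_min - AIC_i) / 2),

with RL <= 0.1 flagged as a significant fit difference. Scaled AIC is the
per-target min-max normalisation of AIC to [0, 1] (heatmap colours).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import Cohort
from .constants import INDICATORS
from .outcomes import fit_cox
from .trajectories import PREDICTOR_SETS, fit_random_intercept
from .treatments import fit_multinomial, step_per_interval

logger = logging.getLogger(__name__)

RL_SIGNIFICANCE = 0.1


def relative_likelihood(aic_values) -> np.ndarray:
    """RL_i = exp((min AIC - AIC_i)/2); the minimiser gets exactly 1."""
    aic = np.asarray(aic_values, dtype=float)
    if aic.size == 0 or not np.all(np.isfinite(aic)):
        raise ValueError("AIC values must be non-empty and finite")
    return np.exp((aic.min() - aic) / 2.0)


def _scaled(aic: np.ndarray) -> np.ndarray:
    rng = aic.max() - aic.min()
    if rng == 0:
        return np.zeros_like(aic)
    return (aic - aic.min()) / rng


def _cox_covariates(baseline_table: pd.DataFrame, labels: pd.Series,
                    predictors: str) -> pd.DataFrame:
    cov = baseline_table.set_index("id")[list(INDICATORS) + ["sex"]].copy()
    out = pd.DataFrame(index=cov.index)
    if predictors in ("subgroups", "both"):
        out["subgroup"] = labels.reindex(cov.index)
    if predictors in ("indicators", "both"):
        for k in INDICATORS:
            out[f"baseline_{k}"] = cov[k]
    return out


def compare_predictor_sets(cohort: Cohort, labels: pd.Series,
                           baseline_table: pd.DataFrame,
                           model_specs: list,
                           reference_subgroup_trajectory: str = "SIDD",
                           reference_subgroup_cox: str = "MDH",
                           reference_subgroup_multinomial: str = "MD",
                           entry_times: pd.Series | None = None) -> pd.DataFrame:
    """Fill the comparison grid for a list of model targets.

    ``model_specs`` entries are ``("trajectory", parameter)``,
    ``("cox", outcome)`` or ``("multinomial",)``. Returns a long table with
    columns target, predictor_set, AIC, scaled_AIC, RL, significant. A fit
    failure leaves the cell missing but keeps the row.
    """
    rows = []
    step_table = None
    for spec in model_specs:
        kind = spec[0]
        if kind not in ("trajectory", "cox", "multinomial"):
            raise ValueError(f"unknown model target kind: {kind!r}")
        target = ":".join(str(s) for s in spec)
        aics = {}
        for pred in PREDICTOR_SETS:
            try:
                if kind == "trajectory":
                    res = fit_random_intercept(
                        cohort, spec[1], pred, labels, baseline_table,
                        reference_subgroup=reference_subgroup_trajectory)
                    aics[pred] = res.aic
                elif kind == "cox":
                    ev = cohort.events[cohort.events["outcome"] == spec[1]]
                    cov = _cox_covariates(baseline_table, labels, pred)
                    res = fit_cox(ev, cov, entry_times=entry_times,
                                  reference=reference_subgroup_cox)
                    aics[pred] = res.aic
                elif kind == "multinomial":
                    if step_table is None:
                        step_table = step_per_interval(cohort)
                    res = fit_multinomial(
                        step_table, pred, labels, cohort.individuals,
                        baseline_table,
                        reference_subgroup=reference_subgroup_multinomial)
                    aics[pred] = res.aic
            except Exception as exc:
                logger.warning("fit failed for %s / %s: %s", target, pred, exc)
                aics[pred] = np.nan
        vals = np.array([aics[p] for p in PREDICTOR_SETS])
        finite = np.isfinite(vals)
        rl = np.full_like(vals, np.nan)
        sc = np.full_like(vals, np.nan)
        if finite.any():
            rl[finite] = relative_likelihood(vals[finite])
            sc[finite] = _scaled(vals[finite])
        for p, a, r, s in zip(PREDICTOR_SETS, vals, rl, sc):
            rows.append({"target": target, "predictor_set": p, "AIC": a,
                         "scaled_AIC": s, "RL": r,
                         "significant": bool(r <= RL_SIGNIFICANCE) if np.isfinite(r) else None})
    return pd.DataFrame(rows)
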