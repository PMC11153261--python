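"""Partition agreement: confusion matrix, accuracy with exact CI, Cohen's
kappa and per-class sensitivity / specificity / specific agreement.

Given a reference and a candidate labelling of the same individuals
(reference on rows), with counts :math:`n_{rc}`, row totals :math:`R_c`,
column totals :math:`C_c` and total :math:`n`:

* accuracy = trace / n, with exact Clopper–Pearson 95% CI;
* Cohen's kappa = (p_o - p_e) / (1 - p_e), p_e from marginal products;
* per class c: sensitivity = n_cc / R_c, specificity =
  (n - R_c - C_c + n_cc) / (n - R_c), and (positive) specific agreement =
  2 n_cc / (R_c + C_c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint


@dataclass
class AgreementReport:
    confusion: pd.DataFrame        # reference rows x candidate columns
    accuracy: float
    accuracy_ci: tuple
    kappa: float
    per_class: pd.DataFrame        # sensitivity, specificity, specific_agreement
    n: int


def compare_partitions(reference_labels, candidate_labels,
                       classes=None) -> AgreementReport:
    """Agreement battery between two equal-length label sequences."""
    ref = pd.Series(reference_labels).reset_index(drop=True)
    cand = pd.Series(candidate_labels).reset_index(drop=True)
    if len(ref) != len(cand):
        raise ValueError(f"length mismatch: {len(ref)} vs {len(cand)}")
    if len(ref) == 0:
        raise ValueError("empty label sequences")
    if classes is None:
        classes = sorted(set(ref) | set(cand))
    classes = list(classes)

    mat = pd.crosstab(ref, cand).reindex(index=classes, columns=classes, fill_value=0)
    mat.index.name, mat.columns.name = "reference", "candidate"
    m = mat.to_numpy(dtype=float)
    n = m.sum()
    trace = np.trace(m)
    accuracy = trace / n
    lo, hi = proportion_confint(int(round(trace)), int(round(n)), alpha=0.05,
                                method="beta")

    row, col = m.sum(axis=1), m.sum(axis=0)
    p_o = trace / n
    p_e = float(np.dot(row, col)) / n**2
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)

    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.diag(m) / row
        spec = (n - row - col + np.diag(m)) / (n - row)
        sa = 2 * np.diag(m) / (row + col)
    per_class = pd.DataFrame(
        {"sensitivity": sens, "specificity": spec, "specific_agreement": sa},
        index=pd.Index(classes, name="class"),
    )
    return AgreementReport(mat, float(accuracy), (float(lo), float(hi)),
                           float(kappa), per_class, int(n))
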