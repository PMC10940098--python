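"""Objective-response analysis and biomarker comparison for the
immunotherapy cohorts.

ORR = (CR + PR) / n per group (RECIST v1.1 categories); group differences
by Pearson chi-square, with Fisher's exact test substituted for 2x2 tables
with any expected cell below 5.  Biomarker comparison uses logistic
combinations of the scores and the DeLong test for correlated ROC curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .roc import delong_paired_test, roc_auc

__all__ = ["RESPONDER_CATEGORIES", "orr_table", "compare_auc",
           "logistic_combination", "AucComparison"]

RESPONDER_CATEGORIES = ("CR", "PR")
_ALL_CATEGORIES = ("CR", "PR", "SD", "PD")


def orr_table(categories, groups) -> tuple[pd.DataFrame, float, str]:
    """Per-group objective response rates with a cross-group test.

    Returns ``(table, p_value, test_name)`` where the table has columns
    n / responders / orr_percent per group.
    """
    cat = np.asarray(categories, dtype=object)
    grp = np.asarray(groups)
    if cat.size == 0:
        raise ValueError("no response records")
    bad = set(cat) - set(_ALL_CATEGORIES)
    if bad:
        raise ValueError(f"unknown response categories: {bad}")
    responder = np.isin(cat, RESPONDER_CATEGORIES)

    labels = [g for g in pd.unique(grp)]
    rows = []
    for g in labels:
        m = grp == g
        n = int(m.sum())
        if n == 0:
            raise ValueError(f"empty group {g!r}")
        r = int(responder[m].sum())
        rows.append({"group": g, "n": n, "responders": r,
                     "orr_percent": 100.0 * r / n})
    table = pd.DataFrame(rows).set_index("group")

    counts = np.array([[row["responders"], row["n"] - row["responders"]]
                       for _, row in table.iterrows()])
    if counts.shape[0] < 2:      # single group: rates only, nothing to test
        return table, float("nan"), "none"
    expected = stats.contingency.expected_freq(counts)
    if counts.shape == (2, 2) and (expected < 5).any():
        _, p = stats.fisher_exact(counts)
        test = "fisher_exact"
    else:
        chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
        test = "chi_square"
        if (expected < 5).any():
            test = "chi_square_small_expected"
    return table, float(p), test


def logistic_combination(score_columns: pd.DataFrame, labels) -> np.ndarray:
    """Fitted logistic linear predictor combining one or more scores
    (used for the LRS+MRS and CPS+LRS+MRS composite markers)."""
    y = np.asarray(labels).astype(int)
    X = score_columns.to_numpy(dtype=float)
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10000)
    model.fit(X, y)
    return X @ model.coef_[0] + model.intercept_[0]


@dataclass
class AucComparison:
    auc_a: float
    auc_b: float
    delta: float
    p_value: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]


def compare_auc(scores_a, scores_b, labels) -> AucComparison:
    """DeLong comparison of two paired scores against the same binary
    outcome."""
    ra = roc_auc(scores_a, labels)
    rb = roc_auc(scores_b, labels)
    auc_a, auc_b, delta, p = delong_paired_test(scores_a, scores_b, labels)
    return AucComparison(auc_a, auc_b, delta, p,
                         (ra.ci_low, ra.ci_high), (rb.ci_low, rb.ci_high))
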