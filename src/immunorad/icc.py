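"""Intraclass correlation for feature reproducibility across repeated
segmentations.

Model: two-way random effects, absolute agreement, single rater — ICC(2,1)
— computed from the ANOVA mean squares

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with n subjects and k raters.  Features with zero between-subject variance
carry no reproducibility information and are returned as 0 with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["icc_2_1", "compute_icc", "IccResult"]


@dataclass
class IccResult:
    value: float
    degenerate: bool = False


def icc_2_1(ratings: np.ndarray) -> IccResult:
    """ICC(2,1) of an (n subjects x k raters) matrix."""
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2:
        raise ValueError("ratings must be 2D (subjects x raters)")
    n, k = X.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 raters")

    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if ss_rows <= 0 and ss_err <= 0:
        return IccResult(0.0, degenerate=True)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return IccResult(0.0, degenerate=True)
    return IccResult(float((msr - mse) / denom))


def compute_icc(ratings_by_feature: dict[str, np.ndarray] | pd.DataFrame,
                intra_by_feature: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """ICC table across features.

    ``ratings_by_feature`` maps feature name -> (subjects x raters) matrix of
    inter-observer repeats; ``intra_by_feature`` likewise for intra-observer
    repeats (optional).  Returns a DataFrame indexed by feature with columns
    ``inter_observer_icc`` (and ``intra_observer_icc``) plus degeneracy flags.
    """
    if isinstance(ratings_by_feature, pd.DataFrame):
        raise TypeError("pass a mapping feature -> (subjects x raters) matrix")
    rows = {}
    for feat, mat in ratings_by_feature.items():
        res = icc_2_1(np.asarray(mat))
        row = {"inter_observer_icc": res.value,
               "inter_degenerate": res.degenerate}
        if intra_by_feature is not None:
            res2 = icc_2_1(np.asarray(intra_by_feature[feat]))
            row["intra_observer_icc"] = res2.value
            row["intra_degenerate"] = res2.degenerate
        rows[feat] = row
    return pd.DataFrame.from_dict(rows, orient="index")
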