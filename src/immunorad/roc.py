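"""ROC/AUC utilities: Mann-Whitney AUC with tie correction, DeLong
variance/CI, DeLong paired test, and the Youden-index cutoff."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AucResult", "roc_auc", "delong_paired_test", "youden_cutoff",
           "alternative_cutoffs"]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components (V10 per positive, V01 per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    allr = _midrank(np.concatenate([pos, neg]))
    rpos = _midrank(pos)
    rneg = _midrank(neg)
    v10 = (allr[:m] - rpos) / n
    v01 = 1.0 - (allr[m:] - rneg) / m
    auc = v10.mean()
    return auc, v10, v01


@dataclass
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float


def roc_auc(scores, labels, alpha: float = 0.05) -> AucResult:
    """AUC by the rank (Mann-Whitney) formulation with tie correction;
    95% CI from the DeLong variance."""
    scores = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    auc, v10, v01 = _delong_components(scores, y)
    var = (np.var(v10, ddof=1) / len(v10) if len(v10) > 1 else 0.0) \
        + (np.var(v01, ddof=1) / len(v01) if len(v01) > 1 else 0.0)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    return AucResult(float(auc), float(np.clip(auc - z * se, 0, 1)),
                     float(np.clip(auc + z * se, 0, 1)), se)


def delong_paired_test(scores_a, scores_b, labels):
    """DeLong test for two correlated ROC curves on the same subjects.

    Returns (auc_a, auc_b, delta, p_two_sided).
    """
    y = _check_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    auc_a, v10a, v01a = _delong_components(a, y)
    auc_b, v10b, v01b = _delong_components(b, y)
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = (np.var(d10, ddof=1) / len(d10) if len(d10) > 1 else 0.0) \
        + (np.var(d01, ddof=1) / len(d01) if len(d01) > 1 else 0.0)
    delta = auc_a - auc_b
    if var <= 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), float(delta), p


def youden_cutoff(scores, labels) -> float:
    """Observed-score threshold maximizing sensitivity + specificity - 1
    under the rule ``high iff score >= cutoff``; ties broken toward the
    smallest maximizing threshold."""
    scores = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    best_c, best_j = None, -np.inf
    for c in np.unique(scores):            # ascending
        pred = scores >= c
        sens = pred[y == 1].mean()
        spec = (~pred)[y == 0].mean()
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c)


def alternative_cutoffs(scores) -> dict[str, float]:
    """Median / quartile cutoffs (linear-interpolation quantiles)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty scores")
    q25, q50, q75 = np.percentile(scores, [25, 50, 75])
    return {"median": float(q50), "upper_quartile": float(q75),
            "lower_quartile": float(q25)}
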