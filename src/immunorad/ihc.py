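"""IHC-derived immune context scores.

Lymphoid immune score (LIS, 0-4): CD3 and CD8 cell counts in the
intratumoral and peritumoral regions each contribute 1 point when the count
is greater than or equal to the training-cohort median for that
marker-region.  Myeloid immune score (MIS, 0-2): likewise for CD66b in the
two regions.  Statuses: LIS low = 0-1, high = 2-4; MIS low = 0, high = 1-2.
Medians are fitted once on the training cohort and applied unchanged to any
validation data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MARKER_REGIONS", "LYMPHOID_KEYS", "MYELOID_KEYS",
           "MedianThresholds", "ImmuneContextScore", "fit_medians",
           "score_patient", "score_table"]

LYMPHOID_KEYS = ("cd3_intra", "cd3_peri", "cd8_intra", "cd8_peri")
MYELOID_KEYS = ("cd66b_intra", "cd66b_peri")
MARKER_REGIONS = LYMPHOID_KEYS + MYELOID_KEYS


@dataclass(frozen=True)
class MedianThresholds:
    """Per marker-region training medians, frozen after fitting."""

    values: tuple[tuple[str, float], ...]

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


@dataclass(frozen=True)
class ImmuneContextScore:
    lis: int
    mis: int

    @property
    def lis_status(self) -> str:
        return "low" if self.lis <= 1 else "high"

    @property
    def mis_status(self) -> str:
        return "low" if self.mis == 0 else "high"


def fit_medians(training_counts: pd.DataFrame) -> MedianThresholds:
    """Empirical median of each marker-region count column (midpoint for
    even n) on the training cohort."""
    if len(training_counts) < 1:
        raise ValueError("need at least one training patient")
    missing = [k for k in MARKER_REGIONS if k not in training_counts.columns]
    if missing:
        raise ValueError(f"missing count columns: {missing}")
    vals = tuple((k, float(np.median(training_counts[k].to_numpy(dtype=float))))
                 for k in MARKER_REGIONS)
    return MedianThresholds(vals)


def score_patient(counts: dict[str, float] | pd.Series,
                  thresholds: MedianThresholds) -> ImmuneContextScore:
    """Additive LIS/MIS for one patient; a count at or above its median
    scores 1."""
    med = thresholds.as_dict()
    for k in MARKER_REGIONS:
        if k not in counts or pd.isna(counts[k]):
            raise ValueError(f"missing count {k!r}")
    lis = sum(int(float(counts[k]) >= med[k]) for k in LYMPHOID_KEYS)
    mis = sum(int(float(counts[k]) >= med[k]) for k in MYELOID_KEYS)
    return ImmuneContextScore(lis=lis, mis=mis)


def score_table(counts: pd.DataFrame,
                thresholds: MedianThresholds) -> pd.DataFrame:
    """Vectorized scoring of a cohort table; returns lis, mis and statuses."""
    med = thresholds.as_dict()
    lis = sum((counts[k].to_numpy(dtype=float) >= med[k]).astype(int)
              for k in LYMPHOID_KEYS)
    mis = sum((counts[k].to_numpy(dtype=float) >= med[k]).astype(int)
              for k in MYELOID_KEYS)
    out = pd.DataFrame(index=counts.index)
    out["lis"] = lis
    out["mis"] = mis
    out["lis_status"] = np.where(out["lis"] <= 1, "low", "high")
    out["mis_status"] = np.where(out["mis"] == 0, "low", "high")
    return out
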