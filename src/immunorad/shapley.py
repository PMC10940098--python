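"""Exact interventional Shapley attribution for scalar prediction models.

The value of a coalition S for instance x is the background-averaged
prediction with features in S taken from x and the rest from each
background row.  Exact enumeration over all 2^p coalitions is available for
p <= 15 features (the intended use — two radiomics scores plus a handful of
clinical covariates — sits well inside that); beyond that a seeded
Monte-Carlo permutation estimator is provided.  The efficiency axiom
holds exactly in enumeration mode: sum_i phi_i(x) = f(x) - E_bg[f].
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

__all__ = ["exact_shapley", "permutation_shapley", "shapley_importance"]

MAX_EXACT_FEATURES = 15


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def exact_shapley(predict, X, background) -> np.ndarray:
    """Exact Shapley values, one row per instance, one column per feature.

    ``predict`` maps an (n, p) array to n scalar predictions (log-odds
    scale for classifiers).
    """
    X = _as_array(X)
    bg = _as_array(background)
    n, p = X.shape
    if p > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{p} features exceed the exact-enumeration limit "
            f"({MAX_EXACT_FEATURES}); use permutation_shapley")
    nb = len(bg)
    weights = {s: factorial(s) * factorial(p - s - 1) / factorial(p)
               for s in range(p)}

    subsets = []
    for size in range(p + 1):
        subsets += [frozenset(c) for c in combinations(range(p), size)]

    phi = np.zeros((n, p))
    for row in range(n):
        x = X[row]
        # coalition value: mean prediction with S from x, rest from background
        values: dict[frozenset, float] = {}
        for S in subsets:
            Z = bg.copy()
            if S:
                Z[:, list(S)] = x[list(S)]
            values[S] = float(predict(Z).mean())
        for i in range(p):
            total = 0.0
            for S in subsets:
                if i in S:
                    continue
                total += weights[len(S)] * (values[S | {i}] - values[S])
            phi[row, i] = total
    return phi


def permutation_shapley(predict, X, background, n_permutations: int = 200,
                        seed: int = 0) -> np.ndarray:
    """Seeded Monte-Carlo permutation estimator of Shapley values (for
    feature counts beyond the exact limit)."""
    X = _as_array(X)
    bg = _as_array(background)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    phi = np.zeros((n, p))
    for row in range(n):
        x = X[row]
        for _ in range(n_permutations):
            perm = rng.permutation(p)
            Z = bg.copy()
            prev = float(predict(Z).mean())
            for i in perm:
                Z[:, i] = x[i]
                cur = float(predict(Z).mean())
                phi[row, i] += cur - prev
                prev = cur
    return phi / n_permutations


def shapley_importance(predict, X, background=None, exact: bool = True,
                       seed: int = 0, n_permutations: int = 200) -> pd.Series:
    """Global importance = mean |Shapley value| per feature over instances."""
    names = (list(X.columns) if isinstance(X, pd.DataFrame)
             else [f"x{i}" for i in range(np.asarray(X).shape[1])])
    if background is None:
        background = X
    if exact:
        phi = exact_shapley(predict, X, background)
    else:
        phi = permutation_shapley(predict, X, background,
                                  n_permutations=n_permutations, seed=seed)
    return pd.Series(np.abs(phi).mean(axis=0), index=names).sort_values(
        ascending=False)
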