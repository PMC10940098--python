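"""Construction of the lymphoid and myeloid radiomics scores (LRS/MRS).

The selection cascade: reproducibility (ICC) filter -> mRMR ranking ->
collinearity reduction -> LASSO logistic and SVM-RFE (each with stratified
5-fold cross-validation) -> overlap of the two supports -> unpenalized
multivariate logistic regression.  The resulting score is the logistic
linear predictor (log-odds); its Youden-index cutoff on the training cohort
dichotomizes patients into low/high status, and the (LRS, MRS) status pair
defines the four radiomics immune subtypes 1 (-/-), 2 (+/-), 3 (-/+),
4 (+/+).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .roc import alternative_cutoffs, roc_auc, youden_cutoff

__all__ = ["zscore_fit_apply", "mrmr_rank", "collinearity_filter",
           "lasso_select", "svmrfe_select", "fit_signature", "assign_subtype",
           "SignatureModel", "SelectionResult", "train_signature",
           "youden_cutoff", "roc_auc", "alternative_cutoffs"]

_EPS = 1e-12


def zscore_fit_apply(train: pd.DataFrame, apply_to: pd.DataFrame | None = None):
    """Standardize columns with training mean and population SD.

    Zero-variance columns are dropped with a warning.  Returns
    (train_z, apply_z, means, sds) where means/sds are Series over the
    retained columns.
    """
    if len(train) < 2:
        raise ValueError("need >= 2 training rows")
    means = train.mean()
    sds = train.std(ddof=0)
    keep = sds[sds > 0].index
    dropped = [c for c in train.columns if c not in set(keep)]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s)",
                      stacklevel=2)
    means, sds = means[keep], sds[keep]
    train_z = (train[keep] - means) / sds
    apply_z = None if apply_to is None else (apply_to[keep] - means) / sds
    return train_z, apply_z, means, sds


def _discretize_ef(col: np.ndarray, bins: int = 3) -> np.ndarray:
    """Equal-frequency discretization used for the mRMR MI estimates."""
    qs = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
    return np.digitize(col, qs)


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI (nats) of two small discrete arrays."""
    ja = np.unique(a, return_inverse=True)[1]
    jb = np.unique(b, return_inverse=True)[1]
    n = len(a)
    joint = np.zeros((ja.max() + 1, jb.max() + 1))
    np.add.at(joint, (ja, jb), 1.0)
    joint /= n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def mrmr_rank(features: pd.DataFrame, labels, k: int) -> list[str]:
    """Greedy max-relevance / min-redundancy ranking (quotient criterion).

    Relevance = MI(feature; label); redundancy = mean MI against the
    already-selected set; both from a 3-bin equal-frequency discretization
    of the features.  Ties resolve to column order.
    """
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("labels must contain both classes")
    if k > features.shape[1]:
        raise ValueError("k exceeds feature count")
    cols = list(features.columns)
    disc = {c: _discretize_ef(features[c].to_numpy(dtype=float)) for c in cols}
    rel = {c: _mutual_information(disc[c], y) for c in cols}

    selected: list[str] = []
    remaining = list(cols)
    while len(selected) < k:
        if not selected:
            scores = {c: rel[c] for c in remaining}
        else:
            scores = {}
            for c in remaining:
                red = np.mean([_mutual_information(disc[c], disc[s])
                               for s in selected])
                scores[c] = rel[c] / max(red, _EPS)
        best = max(remaining, key=lambda c: (scores[c], -remaining.index(c)))
        selected.append(best)
        remaining.remove(best)
    return selected


def collinearity_filter(features: pd.DataFrame, ranked: list[str],
                        r_max: float = 0.9) -> list[str]:
    """Traverse features in rank order, dropping any with |Pearson r| >
    ``r_max`` against an already-kept feature."""
    missing = [c for c in ranked if c not in features.columns]
    if missing:
        raise ValueError(f"ranked names not in matrix: {missing}")
    kept: list[str] = []
    X = {c: features[c].to_numpy(dtype=float) for c in ranked}
    for c in ranked:
        ok = True
        for kcol in kept:
            r = np.corrcoef(X[c], X[kcol])[0, 1]
            if np.isfinite(r) and abs(r) > r_max:
                ok = False
                break
        if ok:
            kept.append(c)
    return kept


def _cv_auc(estimator_factory, X: np.ndarray, y: np.ndarray, folds: int,
            seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        est = estimator_factory()
        est.fit(X[tr], y[tr])
        s = est.decision_function(X[te])
        if y[te].min() == y[te].max():
            continue
        aucs.append(roc_auc(s, y[te]).auc)
    return float(np.mean(aucs)) if aucs else 0.5


def lasso_select(features: pd.DataFrame, labels, folds: int = 5,
                 seed: int = 0, C: float | None = None,
                 c_grid: np.ndarray | None = None) -> list[str]:
    """L1-penalized logistic selection over a 100-point log-spaced penalty
    grid; the penalty maximizing mean cross-validated AUC is kept (ties
    toward the stronger penalty).  ``C`` forces a fixed inverse-penalty."""
    y = np.asarray(labels).astype(int)
    X = features.to_numpy(dtype=float)
    counts = np.bincount(y, minlength=2)
    if C is None and counts.min() < folds:
        raise ValueError("need >= folds samples per class")

    def factory(c):
        return lambda: LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                          C=c, max_iter=5000)

    if C is None:
        grid = np.logspace(-3, 2, 100) if c_grid is None else np.asarray(c_grid)
        grid = np.sort(grid)          # ascending C = descending penalty
        best_c, best_auc = grid[0], -np.inf
        for c in grid:
            auc = _cv_auc(factory(c), X, y, folds, seed)
            if auc > best_auc + 1e-10:
                best_auc, best_c = auc, c
        C = float(best_c)

    model = factory(C)()
    model.fit(X, y)
    sel = [c for c, b in zip(features.columns, model.coef_[0]) if b != 0.0]
    if not sel:
        warnings.warn("LASSO selected no features", stacklevel=2)
    return sel


def svmrfe_select(features: pd.DataFrame, labels, folds: int = 5,
                  seed: int = 0, step_fraction: float = 0.1) -> list[str]:
    """Linear-SVM recursive feature elimination (cost 1).

    At each stage the 10% of features with smallest squared weight are
    removed; the surviving subset size with the best mean cross-validated
    AUC is returned (ties toward the smaller subset).
    """
    y = np.asarray(labels).astype(int)
    cols = list(features.columns)
    if len(cols) == 1:
        return cols
    if np.bincount(y, minlength=2).min() < folds:
        raise ValueError("need >= folds samples per class")

    def factory():
        return SVC(kernel="linear", C=1.0)

    current = list(cols)
    candidates: list[tuple[float, int, tuple[str, ...]]] = []
    while True:
        X = features[current].to_numpy(dtype=float)
        auc = _cv_auc(factory, X, y, folds, seed)
        candidates.append((auc, len(current), tuple(current)))
        if len(current) == 1:
            break
        svm = factory()
        svm.fit(X, y)
        w2 = np.asarray(svm.coef_)[0] ** 2
        n_drop = max(1, int(np.floor(step_fraction * len(current))))
        order = np.argsort(w2, kind="stable")
        drop = {current[i] for i in order[:n_drop]}
        current = [c for c in current if c not in drop]

    best = max(candidates, key=lambda t: (t[0], -t[1]))
    return list(best[2])


@dataclass
class SelectionResult:
    """Stage-by-stage surviving feature names of the cascade."""

    icc_pass: list[str]
    mrmr_top: list[str]
    decorrelated: list[str]
    lasso_set: list[str]
    svmrfe_set: list[str]
    overlap_set: list[str]
    used_fallback: bool = False


@dataclass
class SignatureModel:
    """A trained radiomics score: selected features, logistic coefficients,
    z-normalization parameters and the Youden cutoff."""

    target: str                      # "lymphoid" or "myeloid"
    feature_names: list[str]
    coefficients: np.ndarray         # log-odds units, one per feature
    intercept: float
    norm_means: np.ndarray
    norm_sds: np.ndarray
    cutoff: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.norm_means = np.asarray(self.norm_means, dtype=float)
        self.norm_sds = np.asarray(self.norm_sds, dtype=float)
        if len(self.feature_names) != len(self.coefficients):
            raise ValueError("one coefficient per feature required")
        if np.any(self.norm_sds <= 0):
            raise ValueError("normalization SDs must be positive")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    def score(self, features: pd.DataFrame) -> np.ndarray:
        """Linear predictor (log-odds) for each row."""
        X = features[self.feature_names].to_numpy(dtype=float)
        Z = (X - self.norm_means) / self.norm_sds
        return Z @ self.coefficients + self.intercept

    def status(self, features: pd.DataFrame) -> np.ndarray:
        """'high' iff score >= cutoff."""
        if self.cutoff is None:
            raise ValueError("cutoff not set")
        s = self.score(features)
        return np.where(s >= self.cutoff, "high", "low")

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "target": self.target,
            "feature_names": self.feature_names,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "norm_means": self.norm_means.tolist(),
            "norm_sds": self.norm_sds.tolist(),
            "cutoff": self.cutoff,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SignatureModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(d["target"], d["feature_names"], np.array(d["coefficients"]),
                   d["intercept"], np.array(d["norm_means"]),
                   np.array(d["norm_sds"]), d["cutoff"], d.get("metadata", {}))


def fit_signature(features: pd.DataFrame, labels, overlap: list[str],
                  target: str = "lymphoid") -> SignatureModel:
    """Unpenalized multivariate logistic fit on the overlap features.

    Perfect separation is stabilized with a vanishing ridge (C = 1e6) and
    flagged in the model metadata.
    """
    if not overlap:
        raise ValueError("overlap feature set is empty")
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("labels must contain both classes")
    train_z, _, means, sds = zscore_fit_apply(features[overlap])
    names = list(train_z.columns)
    X = train_z.to_numpy(dtype=float)

    meta: dict = {}
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10000,
                               tol=1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    if np.abs(model.coef_).max() > 30:       # separation blow-up
        model = LogisticRegression(l1_ratio=0.0, C=1e6, solver="lbfgs",
                                   max_iter=10000, tol=1e-12)
        model.fit(X, y)
        meta["separation_stabilized"] = True

    return SignatureModel(target=target, feature_names=names,
                          coefficients=model.coef_[0],
                          intercept=float(model.intercept_[0]),
                          norm_means=means.to_numpy(),
                          norm_sds=sds.to_numpy(), metadata=meta)


_SUBTYPE = {("low", "low"): 1, ("high", "low"): 2,
            ("low", "high"): 3, ("high", "high"): 4}


def assign_subtype(lrs_status: str, mrs_status: str) -> int:
    """Radiomics immune subtype from the (LRS, MRS) status pair:
    1 (-/-), 2 (+/-), 3 (-/+), 4 (+/+)."""
    key = (str(lrs_status), str(mrs_status))
    if key not in _SUBTYPE:
        raise ValueError(f"undefined status pair {key}")
    return _SUBTYPE[key]


def train_signature(features: pd.DataFrame, labels, target: str,
                    seed: int = 0, icc_pass: list[str] | None = None,
                    k_mrmr: int = 30, folds: int = 5,
                    r_max: float = 0.9) -> tuple[SignatureModel, SelectionResult]:
    """Run the full cascade and return the fitted signature with its
    stage-by-stage selection record.

    If the LASSO/SVM-RFE overlap has fewer than 2 features the LASSO set is
    used instead (logged in the selection record and model metadata).
    """
    y = np.asarray(labels).astype(int)
    cols = list(features.columns) if icc_pass is None else list(icc_pass)
    sub = features[cols]
    train_z, _, means, sds = zscore_fit_apply(sub)
    cols = list(train_z.columns)

    k = min(k_mrmr, len(cols))
    ranked = mrmr_rank(train_z, y, k)
    decorr = collinearity_filter(train_z, ranked, r_max=r_max)
    lasso_set = lasso_select(train_z[decorr], y, folds=folds, seed=seed)
    svm_set = svmrfe_select(train_z[decorr], y, folds=folds, seed=seed)
    overlap = [c for c in decorr if c in set(lasso_set) & set(svm_set)]

    used_fallback = False
    if len(overlap) < 2:
        fallback = lasso_set if lasso_set else decorr[: max(1, min(3, len(decorr)))]
        warnings.warn("LASSO/SVM-RFE overlap < 2 features; falling back to "
                      "the LASSO set", stacklevel=2)
        overlap = [c for c in decorr if c in set(fallback)]
        used_fallback = True

    model = fit_signature(features, y, overlap, target=target)
    scores = model.score(features)
    model.cutoff = youden_cutoff(scores, y)
    model.metadata.update({"seed": seed, "folds": folds,
                           "used_fallback": used_fallback})
    sel = SelectionResult(icc_pass=list(sub.columns), mrmr_top=ranked,
                          decorrelated=decorr, lasso_set=lasso_set,
                          svmrfe_set=svm_set, overlap_set=overlap,
                          used_fallback=used_fallback)
    return model, sel
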