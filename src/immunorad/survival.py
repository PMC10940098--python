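"""Survival statistics: Kaplan-Meier, log-rank, Cox proportional hazards
with Schoenfeld-residual PH checking, Harrell's C and the nomogram scoring
mathematics.

The Cox partial likelihood is maximized by Newton iteration (gradient norm
< 1e-8) with Breslow tie handling by default (Efron available), which also
provides the Schoenfeld residuals needed by the proportional-hazards
diagnostic (Grambsch-Therneau correlation test against Kaplan-Meier
transformed event times).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats

__all__ = ["km_estimate", "logrank_test", "cox_fit", "ph_test",
           "concordance_index", "nomogram_model", "CoxResult", "KmResult",
           "PhTestResult", "NomogramModel"]


# ------------------------------------------------------------------ KM

@dataclass
class KmResult:
    timeline: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def km_estimate(time, event, alpha: float = 0.05) -> KmResult:
    """Product-limit estimator with Greenwood confidence bands."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least one record")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(time, event)
    ci = kmf.confidence_interval_survival_function_
    return KmResult(kmf.survival_function_.index.to_numpy(),
                    kmf.survival_function_.iloc[:, 0].to_numpy(),
                    ci.iloc[:, 0].to_numpy(), ci.iloc[:, 1].to_numpy())


def logrank_test(time, event, group):
    """k-sample log-rank test; returns (chi2, df, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if event.sum() == 0:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(time, group, event)
    df = len(labels) - 1
    return float(res.test_statistic), df, float(res.p_value)


# ------------------------------------------------------------------ Cox

@dataclass
class CoxResult:
    names: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    ties: str
    n: int
    n_events: int
    flags: list[str] = field(default_factory=list)
    # sorted copies retained for residual-based diagnostics
    _X: np.ndarray | None = None
    _time: np.ndarray | None = None
    _event: np.ndarray | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.se
        hr = np.exp(self.coef)
        return pd.DataFrame({
            "coef": self.coef, "se": se, "hr": hr,
            "hr_ci_low": np.exp(self.coef - z * se),
            "hr_ci_high": np.exp(self.coef + z * se),
            "p": 2 * stats.norm.sf(np.abs(self.coef) / se),
        }, index=self.names)

    def linear_predictor(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.names].to_numpy(dtype=float)
        return np.asarray(X, dtype=float) @ self.coef


def _risk_set_structure(time, event):
    """Precompute event-time grouping for sorted inputs: first risk-set
    index, event count and rows of each distinct event time."""
    ev_times = np.unique(time[event == 1])
    first = np.searchsorted(time, ev_times, side="left")
    groups = [np.flatnonzero((time == t) & (event == 1)) for t in ev_times]
    d = np.array([len(gr) for gr in groups])
    return first, d, groups


def _cox_derivatives(beta, X, time, event, ties, structure):
    """Breslow/Efron log partial likelihood, gradient and information.

    Inputs must be sorted by ascending time.
    """
    n, p = X.shape
    first, d, groups = structure
    lp = X @ beta
    w = np.exp(lp)
    wx = X * w[:, None]
    wxx = X[:, :, None] * X[:, None, :] * w[:, None, None]
    # suffix (risk set) sums: index i -> sum over j >= i
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ev_rows = np.concatenate(groups) if groups else np.array([], dtype=int)
    ll = float(lp[ev_rows].sum())
    sx = np.add.reduceat(X[ev_rows], np.cumsum(d) - d, axis=0) \
        if len(ev_rows) else np.zeros((0, p))
    g = sx.sum(axis=0)
    info = np.zeros((p, p))

    if ties == "breslow":
        S0 = s0[first]
        S1 = s1[first]
        S2 = s2[first]
        m = S1 / S0[:, None]
        ll -= float((d * np.log(S0)).sum())
        g -= (d[:, None] * m).sum(axis=0)
        info = (d[:, None, None]
                * (S2 / S0[:, None, None]
                   - m[:, :, None] * m[:, None, :])).sum(axis=0)
    else:  # efron
        for k, rows in enumerate(groups):
            dk = d[k]
            S0, S1, S2 = s0[first[k]], s1[first[k]], s2[first[k]]
            e0 = w[rows].sum()
            e1 = wx[rows].sum(axis=0)
            e2 = wxx[rows].sum(axis=0)
            for j in range(dk):
                f = j / dk
                d0 = S0 - f * e0
                d1 = S1 - f * e1
                d2 = S2 - f * e2
                m = d1 / d0
                ll -= np.log(d0)
                g -= m
                info += d2 / d0 - np.outer(m, m)
    return ll, g, info


def cox_fit(X: pd.DataFrame, time, event, ties: str = "breslow",
            max_iter: int = 100, tol: float = 1e-8) -> CoxResult:
    """Cox proportional-hazards fit by Newton maximization of the partial
    likelihood (Breslow ties by default; ``ties="efron"`` available)."""
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events observed")
    if np.linalg.matrix_rank(Xa - Xa.mean(axis=0)) < Xa.shape[1]:
        raise ValueError("design matrix is rank deficient")

    order = np.argsort(time, kind="stable")
    Xs, ts, es = Xa[order], time[order], event[order]

    p = Xa.shape[1]
    beta = np.zeros(p)
    flags: list[str] = []
    structure = _risk_set_structure(ts, es)
    ll, g, info = _cox_derivatives(beta, Xs, ts, es, ties, structure)
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(g) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, g)
        except np.linalg.LinAlgError:
            flags.append("singular information matrix")
            break
        # step halving to guarantee ascent (up to rounding of the loglik)
        ascent_slack = 1e-10 * (1.0 + abs(ll))
        for _half in range(30):
            cand = beta + step
            ll_new, g_new, info_new = _cox_derivatives(cand, Xs, ts, es, ties,
                                                       structure)
            if np.isfinite(ll_new) and ll_new >= ll - ascent_slack:
                break
            step = step / 2
        if abs(ll_new - ll) < 1e-12 * (1.0 + abs(ll)) \
                and np.linalg.norm(cand - beta) < 1e-10:
            beta, ll, g, info = cand, ll_new, g_new, info_new
            converged = True
            break
        beta, ll, g, info = cand, ll_new, g_new, info_new
    else:
        converged = bool(np.linalg.norm(g) < tol)
    if not converged and np.linalg.norm(g) < np.sqrt(tol):
        converged = True            # numerically at the optimum
    if not converged:
        flags.append("non-convergence or separation")
    if np.abs(beta).max() > 15:
        flags.append("possible monotone likelihood (separation)")

    cov = np.linalg.inv(info)
    return CoxResult(names=names, coef=beta, cov=cov, loglik=float(ll),
                     converged=converged, ties=ties, n=len(ts),
                     n_events=int(es.sum()), flags=flags,
                     _X=Xs, _time=ts, _event=es)


# ------------------------------------------------------------------ PH test

@dataclass
class PhTestResult:
    per_covariate: pd.DataFrame     # chi2, p per covariate
    global_chi2: float
    global_df: int
    global_p: float
    verdict: str                     # "violated" if global p < 0.05 else "valid"


def _schoenfeld_residuals(result: CoxResult):
    """Unscaled Schoenfeld residuals (one row per event, sorted by time)."""
    X, time, event = result._X, result._time, result._event
    beta = result.coef
    w = np.exp(X @ beta)
    wx = X * w[:, None]
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    rows, times = [], []
    for i in np.flatnonzero(event == 1):
        first = np.searchsorted(time, time[i], side="left")
        rows.append(X[i] - s1[first] / s0[first])
        times.append(time[i])
    return np.asarray(rows), np.asarray(times)


def ph_test(result: CoxResult, transform: str = "km",
            alpha: float = 0.05) -> PhTestResult:
    """Proportional-hazards diagnostic: correlation of scaled Schoenfeld
    residuals with transformed event times (Grambsch-Therneau), using the
    Kaplan-Meier transform of time by default.  Verdict is "violated" when
    the global p-value is below ``alpha``."""
    if result.n_events < 2:
        raise ValueError("need >= 2 events for the PH test")
    s, ev_times = _schoenfeld_residuals(result)
    d, p = s.shape

    if transform == "km":
        kmf = KaplanMeierFitter()
        kmf.fit(result._time, result._event)
        surv = kmf.survival_function_at_times(ev_times).to_numpy()
        gt = 1.0 - surv
    elif transform == "identity":
        gt = ev_times.astype(float)
    elif transform == "log":
        gt = np.log(ev_times.astype(float))
    else:
        raise ValueError(f"unknown transform {transform!r}")

    xx = gt - gt.mean()
    sxx = float((xx ** 2).sum())
    info_inv = result.cov                      # I(beta)^-1
    u = s.T @ xx                               # p-vector

    chi2_global = float(d / sxx * u @ info_inv @ u)
    p_global = float(stats.chi2.sf(chi2_global, p))

    per = []
    iu = info_inv @ u
    for j in range(p):
        chi2_j = d * iu[j] ** 2 / (info_inv[j, j] * sxx)
        per.append({"chi2": float(chi2_j),
                    "p": float(stats.chi2.sf(chi2_j, 1))})
    per_df = pd.DataFrame(per, index=result.names)
    verdict = "violated" if p_global < alpha else "valid"
    return PhTestResult(per_df, chi2_global, p, p_global, verdict)


# ------------------------------------------------------------- concordance

def concordance_index(linear_predictor, time, event) -> float:
    """Harrell's C for a risk score (higher score = higher risk); predictor
    ties count 1/2."""
    lp = np.asarray(linear_predictor, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no usable pairs (no events)")
    return float(_lifelines_cindex(time, -lp, event))


# --------------------------------------------------------------- nomogram

@dataclass
class NomogramModel:
    """Points mapping of a fitted Cox model: each covariate's contribution
    is scaled so the largest beta x range spans 100 points; total points are
    an increasing affine transform of the linear predictor."""

    names: list[str]
    coef: np.ndarray
    ref: np.ndarray         # covariate value at which points = 0
    scale: float            # points per unit of beta * x

    def covariate_points(self, name: str, x) -> np.ndarray:
        j = self.names.index(name)
        return self.scale * self.coef[j] * (np.asarray(x, dtype=float)
                                            - self.ref[j])

    def total_points(self, X: pd.DataFrame) -> np.ndarray:
        total = np.zeros(len(X))
        for name in self.names:
            total += self.covariate_points(name, X[name].to_numpy(dtype=float))
        return total

    def max_points_per_covariate(self, X: pd.DataFrame) -> dict[str, float]:
        return {n: float(self.covariate_points(n, X[n].to_numpy()).max())
                for n in self.names}


def nomogram_model(result: CoxResult, X: pd.DataFrame) -> NomogramModel:
    """Build the points mapping from a fitted Cox model over cohort ``X``.

    Covariates with degenerate (zero) range are dropped from the point
    scale.  The total-points score preserves the ranking of the linear
    predictor, so its C-index equals the model's.
    """
    names, coefs, refs, spans = [], [], [], []
    for name, b in zip(result.names, result.coef):
        x = X[name].to_numpy(dtype=float)
        rng = x.max() - x.min()
        if rng == 0:
            continue
        names.append(name)
        coefs.append(b)
        refs.append(x.min() if b >= 0 else x.max())
        spans.append(abs(b) * rng)
    if not names:
        raise ValueError("no covariate with nonzero range")
    scale = 100.0 / max(spans)
    return NomogramModel(names, np.asarray(coefs), np.asarray(refs), scale)
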