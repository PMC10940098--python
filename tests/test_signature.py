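"""Feature-selection cascade, logistic signature fitting, Youden cutoff,
subtype assignment and ROC utilities."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import oracles
from immunorad import (alternative_cutoffs, assign_subtype,
                       collinearity_filter, fit_signature, lasso_select,
                       mrmr_rank, roc_auc, svmrfe_select, train_signature,
                       youden_cutoff, zscore_fit_apply)
from immunorad.signature import SignatureModel, _discretize_ef, _mutual_information


class TestZscore:
    def test_hand_zscore_population_sd(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z, _, means, sds = zscore_fit_apply(train)
        np.testing.assert_allclose(z["a"], [-1.2247448, 0.0, 1.2247448],
                                   atol=1e-6)

    def test_apply_equals_train_transform(self):
        train = pd.DataFrame({"a": [1.0, 4.0, 7.0], "b": [0.0, 2.0, 1.0]})
        z, za, _, _ = zscore_fit_apply(train, train)
        pd.testing.assert_frame_equal(z, za)

    def test_constant_column_dropped(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            z, _, _, _ = zscore_fit_apply(train)
        assert list(z.columns) == ["a"]


class TestMrmr:
    def test_label_copy_ranked_first(self, rng):
        y = rng.integers(0, 2, 120)
        X = pd.DataFrame(rng.normal(size=(120, 4)),
                         columns=["n1", "n2", "n3", "n4"])
        X["exact"] = y.astype(float) + rng.normal(0, 1e-6, 120)
        assert mrmr_rank(X, y, 3)[0] == "exact"

    def test_duplicate_not_ranked_second(self, rng):
        y = rng.integers(0, 2, 200)
        info = y + rng.normal(0, 0.3, 200)
        other = y + rng.normal(0, 0.8, 200)
        X = pd.DataFrame({"info": info, "dup": info.copy(), "other": other,
                          "noise": rng.normal(size=200)})
        ranking = mrmr_rank(X, y, 3)
        assert ranking[0] == "info"
        assert ranking[1] != "dup"

    def test_matches_exhaustive_greedy_oracle(self, rng):
        """5-feature toy: ranking equals step-by-step criterion evaluation."""
        y = rng.integers(0, 2, 80)
        X = pd.DataFrame({
            "f1": y + rng.normal(0, 0.4, 80),
            "f2": y + rng.normal(0, 0.7, 80),
            "f3": (y + rng.normal(0, 0.4, 80)),   # near-duplicate of f1 class
            "f4": rng.normal(size=80),
            "f5": rng.normal(size=80)})
        k = 4
        got = mrmr_rank(X, y, k)
        # oracle: recompute the greedy choice at each step from raw MI
        disc = {c: _discretize_ef(X[c].to_numpy()) for c in X.columns}
        rel = {c: _mutual_information(disc[c], y) for c in X.columns}
        selected, remaining = [], list(X.columns)
        for _ in range(k):
            if not selected:
                scores = {c: rel[c] for c in remaining}
            else:
                scores = {c: rel[c] / max(np.mean(
                    [_mutual_information(disc[c], disc[s]) for s in selected]),
                    1e-12) for c in remaining}
            best = max(remaining, key=lambda c: (scores[c], -remaining.index(c)))
            selected.append(best)
            remaining.remove(best)
        assert got == selected


class TestCollinearity:
    def test_identical_columns_lower_ranked_dropped(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        assert collinearity_filter(X, ["a", "b"]) == ["a"]

    def test_uncorrelated_all_kept(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        assert collinearity_filter(X, list("abcd")) == list("abcd")

    def test_hand_correlation_matrix(self, rng):
        base = rng.normal(size=60)
        X = pd.DataFrame({
            "w": base,
            "x": base + rng.normal(0, 0.1, 60),     # r ~ 0.95 with w
            "y": rng.normal(size=60),
            "z": rng.normal(size=60)})
        r = np.corrcoef(X["w"], X["x"])[0, 1]
        assert abs(r) > 0.9
        assert collinearity_filter(X, ["w", "x", "y", "z"]) == ["w", "y", "z"]


class TestLasso:
    def test_max_penalty_empty_selection(self, rng):
        y = rng.integers(0, 2, 60)
        X = pd.DataFrame(rng.normal(size=(60, 5)),
                         columns=[f"f{i}" for i in range(5)])
        with pytest.warns(UserWarning, match="no features"):
            assert lasso_select(X, y, C=1e-4) == []

    def test_orthonormal_design_matches_soft_threshold_support(self, rng):
        """On a near-orthonormal design, the active set at fixed penalty
        agrees with the coordinate soft-threshold condition evaluated on
        the fitted GLM score equations."""
        n = 400
        Q, _ = np.linalg.qr(rng.normal(size=(n, 6)))
        Xm = Q * math.sqrt(n)                      # columns ~ orthonormal
        beta = np.array([1.5, -1.2, 0.8, 0.0, 0.0, 0.0])
        p = 1 / (1 + np.exp(-(Xm @ beta)))
        y = (rng.uniform(size=n) < p).astype(int)
        X = pd.DataFrame(Xm, columns=[f"f{i}" for i in range(6)])
        C = 0.05
        got = set(lasso_select(X, y, C=C))
        # KKT screening oracle: features whose marginal score exceeds the
        # penalty level must be active; clearly sub-threshold ones must not.
        lam = 1.0 / C
        score = np.abs(Xm.T @ (y - y.mean()))
        strong = {f"f{i}" for i in range(6) if score[i] > 1.5 * lam}
        weak = {f"f{i}" for i in range(6) if score[i] < 0.5 * lam}
        assert strong <= got
        assert not (weak & got)

    def test_planted_signal_recovered(self, rng):
        """3 informative of 30 features at 1 SD effect, n = 300."""
        hits = 0
        reps = 25
        for rep in range(reps):
            r = np.random.default_rng(1000 + rep)
            y = r.integers(0, 2, 300)
            X = r.normal(size=(300, 30))
            X[:, :3] += y[:, None] * 1.0
            df = pd.DataFrame(X, columns=[f"f{i}" for i in range(30)])
            sel = set(lasso_select(df, y, seed=rep,
                                   c_grid=np.logspace(-3, 2, 20)))
            if {"f0", "f1", "f2"} <= sel:
                hits += 1
        assert hits >= 0.9 * reps


class TestSvmRfe:
    def test_perfect_feature_survives(self, rng):
        y = rng.integers(0, 2, 80)
        X = pd.DataFrame(rng.normal(size=(80, 8)),
                         columns=[f"f{i}" for i in range(8)])
        X["sep"] = y * 4.0 - 2.0 + rng.normal(0, 0.05, 80)
        assert "sep" in svmrfe_select(X, y, seed=1)

    def test_deterministic_under_seed(self, rng):
        y = rng.integers(0, 2, 60)
        X = pd.DataFrame(rng.normal(size=(60, 10)),
                         columns=[f"f{i}" for i in range(10)])
        X["s"] = y + rng.normal(0, 0.5, 60)
        assert svmrfe_select(X, y, seed=3) == svmrfe_select(X, y, seed=3)

    def test_single_feature_returned(self, rng):
        y = rng.integers(0, 2, 40)
        X = pd.DataFrame({"only": rng.normal(size=40)})
        assert svmrfe_select(X, y) == ["only"]

    def test_elimination_order_matches_weight_ranking(self, rng):
        """First elimination drops the smallest-|w| feature of a full
        retrain, per the RFE definition."""
        from sklearn.svm import SVC
        y = rng.integers(0, 2, 100)
        X = pd.DataFrame({
            "strong": y * 2.0 + rng.normal(0, 0.4, 100),
            "mid": y * 1.0 + rng.normal(0, 0.8, 100),
            "weak": rng.normal(size=100),
            "weak2": rng.normal(size=100)})
        svm = SVC(kernel="linear", C=1.0)
        svm.fit(X.to_numpy(), y)
        w2 = svm.coef_[0] ** 2
        weakest = X.columns[np.argmin(w2)]
        sel = svmrfe_select(X, y, seed=0, step_fraction=0.1)
        # the weakest feature can only appear if the full set won CV
        if weakest in sel:
            assert len(sel) == 4


class TestFitSignature:
    def test_single_feature_matches_newton_oracle(self):
        """Balanced single-feature toy vs an independent likelihood
        maximization (Nelder-Mead on the hand-written log-likelihood)."""
        X = pd.DataFrame({"x": [-1.0] * 50 + [1.0] * 50})
        y = np.array([0] * 50 + [1] * 50)
        # make it non-separable
        y[:5] = 1
        y[50:55] = 0
        model = fit_signature(X, y, ["x"])
        z = zscore_fit_apply(X)[0]["x"].to_numpy()
        res = minimize(lambda p: -oracles.logistic_loglik(p, z[:, None], y),
                       x0=[0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert model.coefficients[0] == pytest.approx(res.x[1], abs=1e-5)
        assert model.intercept == pytest.approx(res.x[0], abs=1e-5)

    def test_score_monotone_in_features(self, rng):
        y = rng.integers(0, 2, 100)
        X = pd.DataFrame({"a": y + rng.normal(0, 0.5, 100),
                          "b": y + rng.normal(0, 0.8, 100)})
        model = fit_signature(X, y, ["a", "b"])
        assert np.all(model.coefficients > 0)
        base = model.score(X)
        bumped = X.copy()
        bumped["a"] += 1.0
        assert np.all(model.score(bumped) > base)

    def test_serialization_round_trip(self, rng, tmp_path):
        y = rng.integers(0, 2, 60)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        X["a"] += y
        model = fit_signature(X, y, ["a", "b", "c"])
        model.cutoff = 0.1
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = SignatureModel.from_json(path)
        np.testing.assert_allclose(loaded.score(X), model.score(X))
        assert loaded.cutoff == model.cutoff

    def test_perfect_separation_stabilized(self):
        X = pd.DataFrame({"x": [-2.0, -1.5, -1.0, 1.0, 1.5, 2.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_signature(X, y, ["x"])
        assert model.metadata.get("separation_stabilized")
        assert np.isfinite(model.coefficients).all()


class TestYouden:
    def test_perfect_separation_cutoff(self):
        assert youden_cutoff([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_worked_six_point_set_matches_scan(self):
        scores = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        labels = [0, 0, 1, 0, 1, 1]
        j, c = oracles.youden_scan_naive(scores, labels)
        got = youden_cutoff(scores, labels)
        assert got == c == 0.3
        # attained J equals the oracle maximum
        pred = np.asarray(scores) >= got
        y = np.asarray(labels)
        j_got = pred[y == 1].mean() + (~pred)[y == 0].mean() - 1
        assert j_got == pytest.approx(j)

    def test_random_scores_match_exhaustive_scan(self, rng):
        for _ in range(20):
            scores = np.round(rng.normal(size=30), 2)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            j_ref, c_ref = oracles.youden_scan_naive(list(scores), list(labels))
            assert youden_cutoff(scores, labels) == pytest.approx(c_ref)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_cutoff([1, 2, 3], [1, 1, 1])


class TestSubtype:
    @pytest.mark.parametrize("pair,expected", [
        (("low", "low"), 1), (("high", "low"), 2),
        (("low", "high"), 3), (("high", "high"), 4)])
    def test_status_pair_mapping(self, pair, expected):
        assert assign_subtype(*pair) == expected

    def test_undefined_status_rejected(self):
        with pytest.raises(ValueError):
            assign_subtype("high", "medium")


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]).auc == 1.0

    def test_pair_enumeration_example(self):
        res = roc_auc([1, 2, 3, 4], [0, 1, 0, 1])
        assert res.auc == pytest.approx(0.75)
        assert res.auc == pytest.approx(
            oracles.auc_pair_count([1, 2, 3, 4], [0, 1, 0, 1]))

    def test_null_auc_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        assert abs(roc_auc(scores, labels).auc - 0.5) < 0.03

    def test_ties_counted_half(self, rng):
        scores = rng.integers(0, 3, 500).astype(float)
        labels = rng.integers(0, 2, 500)
        assert roc_auc(scores, labels).auc == pytest.approx(
            oracles.auc_pair_count(list(scores), list(labels)), abs=1e-12)


class TestAlternativeCutoffs:
    def test_median_of_five(self):
        assert alternative_cutoffs([1, 2, 3, 4, 5])["median"] == 3

    def test_constant_scores_all_equal(self):
        cuts = alternative_cutoffs([2.0, 2.0, 2.0])
        assert len(set(cuts.values())) == 1

    def test_linear_interpolation_quartile(self):
        assert alternative_cutoffs([1, 2, 3, 4])["upper_quartile"] == 3.25


class TestCascade:
    def test_overlap_contained_in_both_supports_and_deterministic(self, rng):
        y = rng.integers(0, 2, 150)
        X = pd.DataFrame(rng.normal(size=(150, 20)),
                         columns=[f"f{i}" for i in range(20)])
        X["f0"] += y * 1.2
        X["f1"] += y * 0.9
        X["f2"] -= y * 1.0
        m1, s1 = train_signature(X, y, "lymphoid", seed=7, k_mrmr=12)
        m2, s2 = train_signature(X, y, "lymphoid", seed=7, k_mrmr=12)
        assert set(s1.overlap_set) <= set(s1.lasso_set) | set()
        if not s1.used_fallback:
            assert set(s1.overlap_set) <= set(s1.svmrfe_set)
        assert set(s1.decorrelated) <= set(s1.mrmr_top)
        assert s1.overlap_set == s2.overlap_set
        np.testing.assert_allclose(m1.score(X), m2.score(X))
        assert m1.cutoff == m2.cutoff

    def test_signature_auc_beats_best_single_feature(self, rng):
        y = rng.integers(0, 2, 200)
        X = pd.DataFrame(rng.normal(size=(200, 10)),
                         columns=[f"f{i}" for i in range(10)])
        X["f0"] += y * 0.8
        X["f1"] += y * 0.8
        model, sel = train_signature(X, y, "lymphoid", seed=2, k_mrmr=8)
        auc_model = roc_auc(model.score(X), y).auc
        best_single = max(max(roc_auc(X[c], y).auc,
                              1 - roc_auc(X[c], y).auc) for c in X.columns)
        assert auc_model >= best_single - 1e-9
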