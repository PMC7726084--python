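"""Univariate screens, bootstrap-LASSO ranking, model-order selection,
ADASYN, KM stratification and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from relomics.modeling import (
    ModelingConfig,
    adasyn_balance,
    bonferroni_threshold,
    bootstrap_lasso_rank,
    calibration_curve,
    cox_univariate,
    km_stratify,
    model_order_select,
    one_se_choice,
    spearman_univariate,
)

FAST = dict(n_bootstrap_rank=15, n_bootstrap_order=25, n_lambda=15, inner_folds=3)


class TestSpearman:
    def test_feature_equals_labels(self):
        rho, _ = spearman_univariate([0, 0, 1, 1, 0, 1], [0, 0, 1, 1, 0, 1])
        assert rho == pytest.approx(1.0)

    def test_feature_negates_labels(self):
        rho, _ = spearman_univariate([1, 1, 0, 0], [0, 0, 1, 1])
        assert rho == pytest.approx(-1.0)

    def test_midrank_hand_value(self):
        # ranks x = 1..4; tied labels get midranks -> rho = 4/sqrt(20)
        rho, p = spearman_univariate([1, 2, 3, 4], [0, 0, 1, 1])
        assert rho == pytest.approx(4 / np.sqrt(20), abs=1e-9)
        assert 0 < p < 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            spearman_univariate([1, 2, 3], [1, 1, 1])


class TestCoxUnivariate:
    def test_perfect_risk_ordering(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        t = np.exp(-x) + 0.01
        with pytest.warns(RuntimeWarning):
            c, hr, _ = cox_univariate(x, t, np.ones(40, int))
        assert c == pytest.approx(1.0)
        assert hr > 1.0

    def test_null_feature_hr_near_one(self):
        rng = np.random.default_rng(1)
        n = 2000
        x = rng.normal(size=n)
        t = rng.exponential(100, n)
        e = (rng.random(n) < 0.7).astype(int)
        _, hr, p = cox_univariate(x, t, e)
        assert hr == pytest.approx(1.0, abs=0.1)
        assert p > 0.001

    def test_c_index_matches_pair_enumeration(self):
        # 6 subjects, one censored; oracle: count comparable pairs by hand
        x = np.array([2.0, 1.0, 0.5, -0.5, -1.0, -2.0])
        t = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        e = np.array([1, 1, 1, 0, 1, 1])
        beta = 1.0  # direction only matters for the c-index of beta*x
        risk = beta * x

        def harrell_oracle():
            num = den = 0.0
            for i in range(6):
                for j in range(6):
                    if i == j:
                        continue
                    # i experiences the event first: comparable
                    if e[i] == 1 and t[i] < t[j]:
                        den += 1
                        if risk[i] > risk[j]:
                            num += 1
                        elif risk[i] == risk[j]:
                            num += 0.5
            return num / den

        c, _, _ = cox_univariate(x, t, e)
        assert c == pytest.approx(harrell_oracle())

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_univariate([1, 2, 3], [1, 2, 3], [0, 0, 0])


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,k,expected", [(0.05, 17, 0.003), (0.05, 47, 0.001), (0.05, 1, 0.05)]
    )
    def test_reported_thresholds(self, alpha, k, expected):
        assert bonferroni_threshold(alpha, k) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestBootstrapLassoRank:
    @pytest.fixture(scope="class")
    def signal_data(self):
        rng = np.random.default_rng(1)
        n = 400
        real = rng.normal(size=n)
        X = pd.DataFrame(
            {"real": real, **{f"noise{i}": rng.normal(size=n) for i in range(10)}}
        )
        y = (rng.random(n) < expit(2 * real)).astype(int)
        return X, y

    def test_true_predictor_ranked_first(self, signal_data):
        X, y = signal_data
        cfg = ModelingConfig(endpoint="OR", seed=0, **FAST)
        rk = bootstrap_lasso_rank(X, y, cfg)
        assert rk.index[0] == "real"
        assert rk.loc["real", "frequency"] > 0.9

    def test_zero_variance_feature_never_selected(self, signal_data):
        X, y = signal_data
        X = X.copy()
        X["flat"] = 3.0
        cfg = ModelingConfig(endpoint="OR", seed=0, **FAST)
        rk = bootstrap_lasso_rank(X, y, cfg)
        assert rk.loc["flat", "frequency"] == 0.0

    def test_column_order_invariance(self, signal_data):
        X, y = signal_data
        cfg = ModelingConfig(endpoint="OR", seed=0, **FAST)
        a = bootstrap_lasso_rank(X, y, cfg)
        b = bootstrap_lasso_rank(X[list(X.columns[::-1])], y, cfg)
        assert a.loc["real", "frequency"] == b.loc["real", "frequency"]
        assert b.index[0] == "real"

    def test_cox_endpoint_finds_signal(self):
        rng = np.random.default_rng(2)
        n = 250
        real = rng.normal(size=n)
        X = pd.DataFrame(
            {"real": real, **{f"noise{i}": rng.normal(size=n) for i in range(6)}}
        )
        t = rng.exponential(1.0 / (0.01 * np.exp(1.5 * real)))
        c = rng.exponential(150.0, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        cfg = ModelingConfig(endpoint="progression", seed=0, **FAST)
        rk = bootstrap_lasso_rank(X, (time, event), cfg)
        assert rk.index[0] == "real"
        assert rk.loc["real", "frequency"] > 0.8

    def test_tiny_sample_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
        X.columns = ["a", "b", "c"]
        cfg = ModelingConfig(endpoint="OR", **FAST)
        with pytest.raises(ValueError, match="n >= 20"):
            bootstrap_lasso_rank(X, np.r_[np.zeros(5), np.ones(5)], cfg)


class TestModelOrder:
    def test_two_feature_outcome_selects_order_two(self):
        rng = np.random.default_rng(10)
        n = 250
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=list("abcdef"))
        y = (rng.random(n) < expit(1.8 * X["a"] + 1.8 * X["b"])).astype(int)
        cfg = ModelingConfig(endpoint="OR", seed=0, **FAST)
        rk = bootstrap_lasso_rank(X, y.to_numpy(), cfg)
        assert set(rk.index[:2]) == {"a", "b"}
        curve = model_order_select(X, y.to_numpy(), rk, cfg)
        assert curve.chosen_order == 2

    def test_noise_outcome_prefers_parsimony(self):
        # pure-noise outcomes: paired bootstrap comparisons make extra
        # features pure overfit, so order 1 wins in most replicates
        chosen = []
        for s in range(5):
            rng = np.random.default_rng(200 + s)
            X = pd.DataFrame(rng.normal(size=(150, 5)), columns=list("abcde"))
            y = rng.integers(0, 2, 150)
            cfg = ModelingConfig(endpoint="OR", seed=s, **FAST)
            rk = bootstrap_lasso_rank(X, y, cfg)
            chosen.append(model_order_select(X, y, rk, cfg).chosen_order)
        assert np.median(chosen) == 1

    def test_one_se_rule_mechanics(self):
        # strictly increasing metric with tiny SE -> chosen = n
        t = pd.DataFrame(
            {"order": [1, 2, 3, 4], "mean": [0.6, 0.7, 0.8, 0.9],
             "se": [1e-6] * 4}
        ).set_index("order")
        assert one_se_choice(t) == 4
        # big SE band -> most parsimonious
        t["se"] = 0.5
        assert one_se_choice(t) == 1
        # rule disabled -> argmax
        assert one_se_choice(t, one_se_rule=False) == 4


class TestADASYN:
    def test_already_balanced_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        X2, y2 = adasyn_balance(X, y)
        assert np.array_equal(X2, X)
        assert np.array_equal(y2, y)

    def test_14_of_103_balanced_to_majority(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (89, 4)), rng.normal(1.5, 1, (14, 4))])
        y = np.r_[np.zeros(89, int), np.ones(14, int)]
        X2, y2 = adasyn_balance(X, y, k=5, rng=rng)
        n_min = (y2 == 1).sum()
        assert abs(n_min - 89) <= 5
        assert (y2 == 0).sum() == 89

    def test_synthetic_points_on_minority_segments(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(2, 1, (10, 2))])
        y = np.r_[np.zeros(40, int), np.ones(10, int)]
        X2, y2 = adasyn_balance(X, y, k=3, rng=rng)
        Xmin = X[y == 1]
        synth = X2[len(X):]
        for s in synth:
            # each synthetic point lies on a segment between two minority pts
            ok = False
            for i in range(len(Xmin)):
                for j in range(len(Xmin)):
                    if i == j:
                        continue
                    d = Xmin[j] - Xmin[i]
                    denom = d @ d
                    if denom == 0:
                        continue
                    lam = (s - Xmin[i]) @ d / denom
                    if -1e-9 <= lam <= 1 + 1e-9 and np.allclose(
                        Xmin[i] + lam * d, s, atol=1e-8
                    ):
                        ok = True
                        break
                if ok:
                    break
            assert ok

    def test_minority_too_small_for_k(self):
        X = np.random.default_rng(3).normal(size=(20, 2))
        y = np.r_[np.zeros(17, int), np.ones(3, int)]
        with pytest.raises(ValueError, match="smaller k"):
            adasyn_balance(X, y, k=5)


class TestKMStratify:
    def test_strong_separation_small_p(self):
        rng = np.random.default_rng(0)
        n = 40
        risk = np.r_[np.ones(20), np.zeros(20)]
        time = np.r_[rng.uniform(5, 30, 20), rng.uniform(200, 400, 20)]
        event = np.ones(n, int)
        out = km_stratify(risk, time, event)
        assert out["logrank_p"] < 0.01
        assert set(out["groups"]) == {"high", "low"}

    def test_identical_groups_p_near_one(self):
        t = np.r_[10, 20, 30, 40, 10, 20, 30, 40.0]
        e = np.ones(8, int)
        risk = np.r_[1, 1, 1, 1, 0, 0, 0, 0.0]
        out = km_stratify(risk, t, e)
        assert out["logrank_p"] > 0.9

    def test_km_estimate_starts_at_one(self):
        rng = np.random.default_rng(1)
        risk = rng.normal(size=30)
        out = km_stratify(risk, rng.uniform(10, 100, 30), np.ones(30, int))
        for kmf in out["curves"].values():
            assert float(kmf.survival_function_.iloc[0]) == pytest.approx(1.0)

    def test_constant_risk_rejected(self):
        with pytest.raises(ValueError, match="stratum"):
            km_stratify(np.ones(10), np.arange(1, 11), np.ones(10, int))


class TestCalibration:
    def test_perfect_calibration(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 8000)
        y = (rng.random(8000) < p).astype(int)
        slope, icpt = calibration_curve(p, y)
        assert slope == pytest.approx(1.0, abs=0.07)
        assert icpt == pytest.approx(0.0, abs=0.07)

    def test_overconfident_predictions_slope_half(self):
        rng = np.random.default_rng(1)
        true_p = rng.uniform(0.05, 0.95, 8000)
        y = (rng.random(8000) < true_p).astype(int)
        overconf = expit(2 * logit(true_p))
        slope, _ = calibration_curve(overconf, y)
        assert slope == pytest.approx(0.5, abs=0.05)

    def test_permuted_labels_slope_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, 4000)
        y = rng.permutation((rng.random(4000) < p).astype(int))
        slope, _ = calibration_curve(p, y)
        assert slope == pytest.approx(0.0, abs=0.1)

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            calibration_curve(np.full(10, 0.4), np.r_[np.zeros(5), np.ones(5)])
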