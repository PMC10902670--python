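import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import cytorisk as cr


def _sim(seed=0, n=37, p=11, informative=3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    k = min(informative, p)
    beta[:k] = [1.2, -1.0, 0.9][:k]
    y = (rng.random(n) < expit(X @ beta - 0.2)).astype(int)
    cols = [f"v{i}" for i in range(p)]
    return pd.DataFrame(X, columns=cols), y


class TestElasticNetFit:
    def test_full_penalty_gives_null_model_with_prevalence_intercept(self):
        X, y = _sim(seed=1)
        m = cr.ElasticNetLogit(mixing=0.5, lam=10.0).fit(X, y)
        assert np.all(m.coef_ == 0.0)
        prev = y.mean()
        assert m.intercept_ == pytest.approx(np.log(prev / (1 - prev)),
                                             abs=1e-6)

    def test_matches_sklearn_saga_oracle_at_fixed_lambda(self):
        from sklearn.linear_model import LogisticRegression

        X, y = _sim(seed=2)
        lam, mix = 0.05, 0.5
        mine = cr.ElasticNetLogit(mixing=mix, lam=lam).fit(X, y)
        Xs = (X - X.mean()) / X.std(ddof=1)
        sk = LogisticRegression(penalty="elasticnet", solver="saga",
                                l1_ratio=mix, C=1.0 / (lam * len(y)),
                                max_iter=100000, tol=1e-10).fit(Xs, y)
        assert np.allclose(mine.coef_std_, sk.coef_[0], atol=1e-5)
        assert mine.intercept_std_ == pytest.approx(sk.intercept_[0],
                                                    abs=1e-5)

    def test_pure_ridge_small_lambda_matches_unpenalized_limit(self):
        import statsmodels.api as sm

        X, y = _sim(seed=3, p=4, informative=2)
        mine = cr.ElasticNetLogit(mixing=0.0, lam=1e-6).fit(X, y)
        fit = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=0)
        assert np.allclose(mine.coef_, fit.params[1:], atol=1e-3)

    def test_kkt_conditions_hold(self):
        X, y = _sim(seed=4)
        m = cr.fit_elastic_net(X, y, seed=0)
        assert m.kkt_residual(X, y) < 1e-6

    def test_objective_trace_non_increasing(self):
        X, y = _sim(seed=5)
        m = cr.ElasticNetLogit(mixing=0.5, lam=0.02).fit(X, y)
        assert np.all(np.diff(m.objective_trace_) <= 1e-12)

    def test_planted_features_selected(self):
        # strong planted effects so cross-validation keeps a non-null model
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.standard_normal((37, 11)),
                         columns=[f"v{i}" for i in range(11)])
        eta = 2.5 * X["v0"] - 2.0 * X["v1"] + 1.8 * X["v2"]
        y = (rng.random(37) < expit(eta)).astype(int)
        m = cr.fit_elastic_net(X, y, seed=0)
        assert set(m.selected_features_) & {"v0", "v1", "v2"}

    def test_standardize_then_fit_equals_internal_standardization(self):
        X, y = _sim(seed=7)
        lam = 0.03
        m1 = cr.ElasticNetLogit(mixing=0.5, lam=lam).fit(X, y)
        Xs = (X - X.mean()) / X.std(ddof=1)
        m2 = cr.ElasticNetLogit(mixing=0.5, lam=lam).fit(Xs, y)
        p1 = m1.predicted_scores(X.to_numpy())
        p2 = m2.predicted_scores(Xs.to_numpy())
        assert np.allclose(p1, p2, atol=1e-8)

    def test_score_monotone_in_each_selected_feature(self):
        X, y = _sim(seed=8)
        m = cr.fit_elastic_net(X, y, seed=0)
        base = X.iloc[[0]].to_numpy().copy()
        for j, (name, b) in enumerate(zip(m.feature_names_in_, m.coef_)):
            if b == 0:
                continue
            up = base.copy()
            up[0, j] += 1.0
            delta = m.predicted_scores(up) - m.predicted_scores(base)
            assert np.sign(delta[0]) == np.sign(b)

    def test_invalid_inputs(self):
        X, y = _sim(seed=9)
        with pytest.raises(ValueError, match="two classes"):
            cr.ElasticNetLogit().fit(X, np.zeros(len(X)))
        with pytest.raises(ValueError, match="mixing"):
            cr.ElasticNetLogit(mixing=1.5, lam=0.1).fit(X, y)
        with pytest.raises(ValueError, match="empty lambda"):
            cr.fit_elastic_net(X, y, lambda_grid=[])

    def test_serialization_roundtrip_fields(self, tmp_path):
        X, y = _sim(seed=10)
        m = cr.ElasticNetLogit(mixing=0.5, lam=0.05).fit(X, y)
        path = tmp_path / "model.json"
        m.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["mixing"] == 0.5
        assert payload["intercept"] == pytest.approx(m.intercept_)
        assert set(payload["coefficients"]) == set(X.columns)


class TestPredictedScore:
    def test_null_model_scores_half(self):
        X, y = _sim(seed=11)
        m = cr.ElasticNetLogit(mixing=0.5, lam=10.0).fit(X, y)
        m.intercept_ = 0.0
        assert cr.predicted_score(m, {}) == 0.5

    def test_closed_form_value(self):
        X, y = _sim(seed=12, p=2)
        m = cr.ElasticNetLogit(mixing=0.5, lam=0.05).fit(X, y)
        m.intercept_ = 1.0
        m.coef_ = np.array([2.0, 0.0])
        s = cr.predicted_score(m, {"v0": 1.0})
        assert s == pytest.approx(np.exp(3) / (1 + np.exp(3)), abs=1e-12)

    def test_logistic_symmetry(self):
        X, y = _sim(seed=13, p=2)
        m = cr.ElasticNetLogit(mixing=0.5, lam=0.05).fit(X, y)
        m.intercept_ = 0.3
        m.coef_ = np.array([1.1, -0.4])
        v = {"v0": 0.7, "v1": -1.2}
        neg = {"v0": -0.7, "v1": 1.2}
        m2_intercept = -0.3
        s = cr.predicted_score(m, v)
        m.intercept_ = m2_intercept
        assert cr.predicted_score(m, neg) == pytest.approx(1 - s, abs=1e-12)

    def test_missing_feature_raises(self):
        X, y = _sim(seed=14, p=2)
        m = cr.ElasticNetLogit(mixing=0.5, lam=0.001).fit(X, y)
        if not m.selected_features_:
            pytest.skip("null fit")
        with pytest.raises(KeyError):
            cr.predicted_score(m, {})

    def test_numerically_stable_for_extreme_predictors(self):
        X, y = _sim(seed=15, p=1, informative=1)
        m = cr.ElasticNetLogit(mixing=0.5, lam=0.05).fit(X, y)
        m.intercept_ = 0.0
        m.coef_ = np.array([1.0])
        assert cr.predicted_score(m, {"v0": 800.0}) == 1.0
        assert cr.predicted_score(m, {"v0": -800.0}) == 0.0


class TestEvaluateScore:
    def test_deterministic_and_delegates(self):
        rng = np.random.default_rng(16)
        s = rng.uniform(size=40)
        y = rng.integers(0, 2, 40)
        a = cr.evaluate_score(s, y, reps=100, seed=3)
        b = cr.evaluate_score(s, y, reps=100, seed=3)
        assert a == b
        assert a["auroc"] == cr.auroc(s, y)

    def test_shuffled_labels_center_auroc_at_half(self):
        rng = np.random.default_rng(17)
        s = rng.uniform(size=60)
        aucs = [cr.auroc(s, rng.permutation([0] * 30 + [1] * 30))
                for _ in range(200)]
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_in_sample_optimism(self):
        # in-sample AUROC of a fitted score exceeds held-out AUROC on average
        ins, outs = [], []
        for seed in range(6):
            X, y = _sim(seed=100 + seed, n=60)
            if len(np.unique(y[:30])) < 2 or len(np.unique(y[30:])) < 2:
                continue
            m = cr.ElasticNetLogit(mixing=0.5, lam=0.01).fit(X.iloc[:30],
                                                             y[:30])
            ins.append(cr.auroc(m.predicted_scores(X.iloc[:30].to_numpy()),
                                y[:30]))
            outs.append(cr.auroc(m.predicted_scores(X.iloc[30:].to_numpy()),
                                 y[30:]))
        assert np.mean(ins) > np.mean(outs)
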