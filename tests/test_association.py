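import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cytorisk as cr


class TestAUROC:
    def test_perfect_separation(self):
        assert cr.auroc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert cr.auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_enumerated_concordant_pairs(self):
        # 3 of 4 positive/negative pairs concordant
        assert cr.auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_matches_sklearn_on_random_data(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(25):
            s = rng.normal(size=30).round(1)  # rounding makes ties
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            assert cr.auroc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_negation_symmetry(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        assert cr.auroc(s, y) + cr.auroc(-s, y) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cr.auroc([1, 2, 3], [1, 1, 1])


class TestBootstrapCI:
    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(2)
        s, y = rng.normal(size=40), rng.integers(0, 2, 40)
        a = cr.bootstrap_auroc_ci(s, y, reps=200, seed=5)
        b = cr.bootstrap_auroc_ci(s, y, reps=200, seed=5)
        assert a == b

    def test_perfectly_separated_interval_is_degenerate_at_one(self):
        s = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.zeros(20), np.ones(20)]
        lo, hi = cr.bootstrap_auroc_ci(s, y, reps=100, seed=0)
        assert lo == hi == 1.0

    def test_interval_brackets_point_estimate_typically(self):
        rng = np.random.default_rng(3)
        s = np.r_[rng.normal(0, 1, 30), rng.normal(1, 1, 30)]
        y = np.r_[np.zeros(30), np.ones(30)]
        lo, hi = cr.bootstrap_auroc_ci(s, y, reps=500, seed=1)
        assert lo <= cr.auroc(s, y) <= hi

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            cr.bootstrap_auroc_ci([1, 2], [0, 1], reps=1)


class TestSpearman:
    def test_monotone_relationship_is_one(self):
        x = np.arange(10.0)
        rho, _ = cr.spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_hand_computed_example(self):
        rho, _ = cr.spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)  # 1 - 6*6/(3*8)

    def test_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = rng.integers(4, 9)
            x = rng.normal(size=n).round(1)
            y = rng.normal(size=n).round(1)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            rho, _ = cr.spearman(x, y)
            assert abs(rho - oracle) < 1e-12

    def test_exact_p_matches_permutation_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 6
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rho, p = cr.spearman(x, y)
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            obs = abs(np.corrcoef(rx, ry)[0, 1])
            count = sum(
                abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12
                for perm in itertools.permutations(ry)
            )
            import math

            assert p == pytest.approx(count / math.factorial(n))

    def test_invariance_to_monotone_transform(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r1, _ = cr.spearman(x, y)
        r2, _ = cr.spearman(np.exp(x), y**3)
        assert r1 == pytest.approx(r2)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            cr.spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestQValues:
    def test_all_ones_stay_one(self):
        assert np.all(cr.qvalues(np.ones(20)) == 1.0)

    def test_equals_benjamini_hochberg_when_pi0_is_one(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=100)
        q = cr.qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh, atol=1e-12)

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(8)
        p = np.sort(rng.uniform(size=60))
        q = cr.qvalues(p)
        assert np.all(np.diff(q) >= -1e-12)

    def test_range_and_nan_rejection(self):
        with pytest.raises(ValueError):
            cr.qvalues([0.1, np.nan])
        with pytest.raises(ValueError):
            cr.qvalues([-0.1, 0.5])
        q = cr.qvalues(np.r_[np.full(50, 1e-6), np.random.default_rng(9)
                             .uniform(size=150)])
        assert np.all((q >= 0) & (q <= 1))


class TestGroupCompare:
    def test_exact_small_sample(self):
        # (1,2) vs (3,4): U = 0, two-sided exact p = 2/C(4,2)
        u, p = cr.group_compare([1, 2, 3, 4], [1, 1, 0, 0])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_matches_assignment_enumeration(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=8)
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        u_obs, p = cr.group_compare(v, labels)
        # enumerate all C(8,3) group assignments of the observed values
        stat = []
        for pos in itertools.combinations(range(8), 3):
            lab = np.zeros(8, int)
            lab[list(pos)] = 1
            u, _ = stats.mannwhitneyu(v[lab == 1], v[lab == 0],
                                      alternative="two-sided")
            stat.append(u)
        stat = np.array(stat)
        n1, n0 = 3, 5
        dev = np.abs(stat - n1 * n0 / 2)
        p_enum = np.mean(dev >= abs(u_obs - n1 * n0 / 2) - 1e-12)
        assert p == pytest.approx(p_enum)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cr.group_compare([1, 2, 3], [1, 1, 1])


class TestFisherExact:
    def test_hypergeometric_sum_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            p = cr.fisher_exact_test(t)
            # oracle: sum hypergeometric pmf over tables <= observed pmf
            r1, r2 = t[0].sum(), t[1].sum()
            c1 = t[:, 0].sum()
            n = t.sum()
            obs = stats.hypergeom.pmf(t[0, 0], n, r1, c1)
            total = sum(
                pm for k in range(max(0, c1 - r2), min(r1, c1) + 1)
                if (pm := stats.hypergeom.pmf(k, n, r1, c1)) <= obs * (1 + 1e-9)
            )
            assert p == pytest.approx(total, rel=1e-6)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            cr.fisher_exact_test([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            cr.fisher_exact_test([[-1, 2], [3, 4]])


class TestOddsRatios:
    def test_matches_maximum_likelihood_oracle(self):
        from scipy.optimize import minimize

        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.normal(size=40)
            y = (rng.random(40) < 1 / (1 + np.exp(-(0.8 * x)))).astype(int)
            if y.min() == y.max():
                continue
            out = cr.feature_odds_ratios(pd.DataFrame({"f": x}), y)

            def nll(b):
                eta = b[0] + b[1] * x
                return np.sum(np.logaddexp(0, eta) - y * eta)

            opt = minimize(nll, [0.0, 0.0], method="BFGS")
            assert np.log(out.loc["f", "odds_ratio"]) == pytest.approx(
                opt.x[1], abs=1e-5)

    def test_positive_association_gives_or_above_one(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=60)
        y = ((x + rng.normal(0, 0.8, 60)) > np.median(x)).astype(int)
        out = cr.feature_odds_ratios(pd.DataFrame({"f": x}), y)
        assert out.loc["f", "odds_ratio"] > 1.0

    def test_null_feature_type_one_error_calibrated(self):
        rng = np.random.default_rng(14)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            x = rng.normal(size=40)
            y = rng.integers(0, 2, 40)
            if y.min() == y.max():
                continue
            out = cr.feature_odds_ratios(pd.DataFrame({"f": x}), y)
            rejections += out.loc["f", "p_value"] < 0.05
        assert 0.02 <= rejections / n_sim <= 0.09

    def test_perfect_separation_flagged_infinite(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        with pytest.warns(UserWarning, match="separation"):
            out = cr.feature_odds_ratios(pd.DataFrame({"f": x}), y)
        assert out.loc["f", "separated"]
        assert np.isinf(out.loc["f", "odds_ratio"])


class TestScreening:
    def test_largest_auroc_coordinate_selected(self):
        rng = np.random.default_rng(15)
        idx = pd.Index([f"P{i}" for i in range(30)])
        y = pd.Series(rng.integers(0, 2, 30), index=idx)
        coords = pd.DataFrame({
            "coordinate 1": rng.normal(size=30),
            "coordinate 2": y + rng.normal(0, 0.3, 30),
        }, index=idx)
        res = cr.screen_coordinates(coords, y, reps=100, seed=0)
        assert res.selected == "coordinate 2"
        assert ((res.table["auroc"] >= 0) & (res.table["auroc"] <= 1)).all()

    def test_correlate_features_flags_strong_feature(self):
        rng = np.random.default_rng(16)
        idx = pd.Index([f"P{i}" for i in range(30)])
        coord = pd.Series(rng.normal(size=30), index=idx)
        feats = pd.DataFrame(rng.normal(size=(30, 40)), index=idx)
        feats.columns = [f"f{i}" for i in range(40)]
        feats["f0"] = coord + rng.normal(0, 0.1, 30)
        out = cr.correlate_features(feats, coord)
        assert bool(out.loc["f0", "significant"])
        assert out["rho"].abs().max() <= 1.0
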