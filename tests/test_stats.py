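import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import lipidrank as lr
from lipidrank.core import LipidDataError
from lipidrank.stats import replay_steps, sequential_logistic_selection


def welch_oracle(a, b, conf=0.95):
    """Independent textbook implementation of the Welch t test."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se = math.sqrt(va / na + vb / nb)
    t = (ma - mb) / se
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(1 - (1 - conf) / 2, df)
    return t, df, p, (ma - mb - tcrit * se, ma - mb + tcrit * se)


class TestWelch:
    def test_frozen_example(self):
        r = lr.welch_test([1, 2, 3], [2, 4, 6])
        assert r.t == pytest.approx(-1.549, abs=1e-3)
        assert r.df == pytest.approx(2.941, abs=1e-3)
        assert r.p == pytest.approx(0.2209, abs=1e-3)

    def test_matches_independent_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                           rng.integers(3, 12)).tolist()
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                           rng.integers(3, 12)).tolist()
            r = lr.welch_test(a, b)
            t, df, p, ci = welch_oracle(a, b)
            assert r.t == pytest.approx(t)
            assert r.df == pytest.approx(df)
            assert r.p == pytest.approx(p)
            assert r.ci_low == pytest.approx(ci[0])
            assert r.ci_high == pytest.approx(ci[1])

    def test_identical_samples_null(self):
        r = lr.welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0
        assert r.p == pytest.approx(1.0)
        assert r.ci_low == pytest.approx(-r.ci_high)

    def test_swap_symmetry(self):
        a, b = [1.0, 2.5, 3.0, 4.0], [2.0, 2.2, 5.0]
        r1, r2 = lr.welch_test(a, b), lr.welch_test(b, a)
        assert r1.p == pytest.approx(r2.p)
        assert r1.ci_low == pytest.approx(-r2.ci_high)
        assert r1.ci_high == pytest.approx(-r2.ci_low)

    def test_constant_equal_groups(self):
        r = lr.welch_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert (r.t, r.p) == (0.0, 1.0)

    def test_zero_variance_unequal_means_is_error(self):
        with pytest.raises(LipidDataError, match="zero variance"):
            lr.welch_test([1.0, 1.0], [2.0, 2.0])

    def test_missing_values_dropped(self):
        r1 = lr.welch_test([1, 2, np.nan, 3], [2, 4, 6])
        r2 = lr.welch_test([1, 2, 3], [2, 4, 6])
        assert r1.t == pytest.approx(r2.t)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 17, 0.0029),
        (0.05, 1, 0.05),
        (0.05, 34, 0.0015),
    ])
    def test_thresholds(self, alpha, m, expected):
        assert lr.bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_raw_value(self):
        assert lr.bonferroni_threshold(0.05, 17, digits=None) == 0.05 / 17


class TestLog2FoldChange:
    def test_equal_means_is_zero(self):
        assert lr.log2_fold_change([1, 3], [2, 2]) == 0.0

    def test_fourfold_is_two(self):
        assert lr.log2_fold_change([4.0, 4.0], [1.0, 1.0]) == 2.0

    def test_record_shape_with_welch(self):
        rng = np.random.default_rng(0)
        case = rng.lognormal(1.0, 0.3, 20)
        ctrl = rng.lognormal(0.0, 0.3, 20)
        fc = lr.log2_fold_change(case, ctrl)
        w = lr.welch_test(case, ctrl)
        assert fc > 0 and w.p < 0.05


class TestUnivariateLogistic:
    def test_strong_spike_detected(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 50 + [0] * 50)
        x = rng.normal(0, 1, 100) + 1.5 * y
        r = lr.univariate_logistic(x, y)
        assert not r.separated
        assert r.coef > 0 and r.p < 0.05

    def test_perfect_separation_flagged(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        r = lr.univariate_logistic(y.astype(float), y)
        assert r.separated and r.p is None

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 60 + [0] * 60)
        pvals = []
        for _ in range(200):
            x = rng.normal(0, 1, 120)
            r = lr.univariate_logistic(x, y)
            pvals.append(r.p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


@pytest.fixture(scope="module")
def unique_signal():
    rng = np.random.default_rng(3)
    n = 150
    X = pd.DataFrame({"A": rng.normal(size=n), "B": rng.normal(size=n),
                      "C": rng.normal(size=n)})
    y = (rng.random(n) < 1 / (1 + np.exp(-3 * X["A"]))).astype(int)
    return X, y.to_numpy()


class TestSequentialSelection:
    @pytest.mark.parametrize("method", ["SFS", "SBS", "SFFS"])
    def test_unique_signal_selected_by_every_method(self, unique_signal,
                                                    method):
        X, y = unique_signal
        res = sequential_logistic_selection(X, y, method=method)
        assert res.selected == ["A"]

    def test_sffs_matches_exhaustive_best_subset(self):
        from itertools import combinations
        from lipidrank.stats import _logit_llf
        for seed in (0, 3, 7, 11):
            rng = np.random.default_rng(seed)
            n, p = 120, 5
            X = pd.DataFrame(rng.normal(size=(n, p)),
                             columns=[f"x{i}" for i in range(p)])
            beta = np.array([1.5, -1.2, 0, 0, 0.8])
            y = (rng.random(n)
                 < 1 / (1 + np.exp(-X.to_numpy() @ beta))).astype(int)
            res = sequential_logistic_selection(X, y, method="SFFS")
            k = len(res.selected)
            best = max(combinations(X.columns, k),
                       key=lambda c: _logit_llf(X, y, c))
            assert set(res.selected) == set(best)

    def test_complementary_pair_recovered_over_marginal_proxy(self):
        rng = np.random.default_rng(7)
        n = 200
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        z = x1 + x2
        X = pd.DataFrame({"proxy": z + rng.normal(scale=2.0, size=n),
                          "x1": x1, "x2": x2,
                          "noise": rng.normal(size=n)})
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * z))).astype(int)
        res = sequential_logistic_selection(X, y, method="SFFS")
        assert set(res.selected) == {"x1", "x2"}

    def test_sbs_is_fixed_point_of_sfs_result(self, unique_signal):
        rng = np.random.default_rng(9)
        X, y = unique_signal
        X = X.copy()
        X["A2"] = X["A"] * 0.8 + rng.normal(scale=0.5, size=len(X))
        sfs = sequential_logistic_selection(X, y, method="SFS")
        if len(sfs.selected) >= 2:
            sbs = sequential_logistic_selection(X[sfs.selected], y,
                                                method="SBS")
            # nothing removable: backward pass keeps the forward solution
            assert set(sbs.selected) <= set(sfs.selected)

    def test_step_log_replays(self, unique_signal):
        X, y = unique_signal
        for method in ("SFS", "SBS", "SFFS"):
            res = sequential_logistic_selection(X, y, method=method)
            assert replay_steps(X, y, res)

    def test_no_candidate_meets_threshold(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
        y = np.array([1] * 40 + [0] * 40)
        res = sequential_logistic_selection(X, y, method="SFS",
                                            enter_p=1e-6)
        assert res.selected == []


class TestRidgeDirection:
    def _cohort(self, shift, seed=0, n=60):
        rng = np.random.default_rng(seed)
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        x = rng.normal(0, 1, n) + shift * y
        return pd.DataFrame({"f": x, "g": rng.normal(size=n)}), y

    def test_higher_case_mean_is_positive(self):
        X, y = self._cohort(2.0)
        d = lr.ridge_direction(X, y, penalty=1.0)
        assert d.direction_of("f") == "Positive"

    def test_lower_case_mean_is_negative(self):
        X, y = self._cohort(-2.0)
        d = lr.ridge_direction(X, y, penalty=1.0)
        assert d.direction_of("f") == "Negative"

    def test_duplicated_features_share_coefficient(self):
        X, y = self._cohort(1.5, seed=2)
        X["f2"] = X["f"]
        d = lr.ridge_direction(X, y, penalty=1.0)
        c = d.table.set_index("feature")["coef"]
        assert c["f"] == pytest.approx(c["f2"], rel=1e-4)
        assert d.direction_of("f") == d.direction_of("f2")

    def test_label_swap_flips_directions(self):
        X, y = self._cohort(2.0, seed=3)
        d1 = lr.ridge_direction(X, y, penalty=1.0)
        d2 = lr.ridge_direction(X, 1 - y, penalty=1.0)
        assert d1.direction_of("f") != d2.direction_of("f")

    def test_cv_penalty_is_recorded_and_deterministic(self):
        X, y = self._cohort(1.0, seed=4)
        d1 = lr.ridge_direction(X, y, seed=1)
        d2 = lr.ridge_direction(X, y, seed=1)
        assert d1.penalty == d2.penalty > 0
        pd.testing.assert_frame_equal(d1.table, d2.table)

    def test_linear_model_flag(self):
        X, y = self._cohort(2.0, seed=5)
        d = lr.ridge_direction(X, y, model="linear")
        assert d.model == "linear"
        assert d.direction_of("f") == "Positive"
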