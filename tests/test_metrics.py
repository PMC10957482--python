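"""Metric implementations checked against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from lesionfm import (auc_roc, balanced_accuracy, bootstrap_ci, cox_univariate,
                      km_logrank, mean_average_precision, permutation_compare,
                      wilcoxon_signed_rank)


# ---------------------------------------------------------------------------
# oracles (independent of the implementation path)


def oracle_balanced_accuracy(y_true, y_pred):
    recalls = []
    for c in np.unique(y_true):
        sel = y_true == c
        recalls.append(np.mean(y_pred[sel] == c))
    return float(np.mean(recalls))


def oracle_average_precision(y_true01, scores):
    """Precision walk: AP = mean of precision at each positive, in rank order."""
    order = np.argsort(-scores, kind="stable")
    y = y_true01[order]
    precisions = []
    tp = 0
    for i, yi in enumerate(y, start=1):
        if yi == 1:
            tp += 1
            precisions.append(tp / i)
    return float(np.mean(precisions))


def oracle_auc(y_true01, scores):
    """Exhaustive concordant-pair count, ties counted half."""
    pos = scores[y_true01 == 1]
    neg = scores[y_true01 == 0]
    total = wins = 0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                wins += 1
            elif p == q:
                wins += 0.5
    return wins / total


def oracle_logrank(times, events, group):
    """Two-sample log-rank statistic from the O-E/V table walk."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def oracle_wilcoxon(x, y):
    """Exact two-sided p by enumeration over all sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    w_all = []
    for signs in itertools.product([0, 1], repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.asarray(w_all)
    mean_w = n * (n + 1) / 4
    p = np.mean(np.abs(w_all - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return float(p)


# ---------------------------------------------------------------------------


class TestBalancedAccuracy:
    def test_perfect(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        prob = np.eye(3)[y]
        assert balanced_accuracy(y, prob) == 1.0

    def test_hand_table(self):
        # class 0: 4/5 correct (recall .8); class 1: 3/5 correct (recall .6)
        y = np.array([0] * 5 + [1] * 5)
        pred = np.array([0, 0, 0, 0, 1, 1, 1, 1, 0, 0])
        prob = np.eye(2)[pred]
        assert balanced_accuracy(y, prob) == pytest.approx(0.7)

    def test_constant_predictor_on_balanced_classes(self):
        y = np.repeat(np.arange(4), 5)
        prob = np.zeros((20, 4))
        prob[:, 2] = 1.0
        assert balanced_accuracy(y, prob) == pytest.approx(0.25)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.zeros(5, int), np.zeros((5, 2)))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = rng.integers(6, 20), rng.integers(2, 4)
        y = np.concatenate([np.arange(k), rng.integers(0, k, size=n - k)])
        prob = rng.dirichlet(np.ones(k), size=n)
        got = balanced_accuracy(y, prob)
        pred = prob.argmax(axis=1) if k > 2 else (prob[:, 1] >= 0.5).astype(int)
        assert got == pytest.approx(oracle_balanced_accuracy(y, pred))

    def test_equals_accuracy_when_balanced(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1, 2], 10)
        prob = rng.dirichlet(np.ones(3), size=30)
        pred = prob.argmax(axis=1)
        assert balanced_accuracy(y, prob) == pytest.approx(np.mean(pred == y))


class TestMeanAveragePrecision:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        prob = np.column_stack([[0.9, 0.8, 0.1, 0.2], [0.1, 0.2, 0.9, 0.8]])
        assert mean_average_precision(y, prob) == 1.0

    def test_five_case_toy_vs_oracle(self):
        y01 = np.array([1, 0, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.4, 0.3, 0.1])
        got = mean_average_precision(y01, np.column_stack([1 - s, s]))
        ap_pos = oracle_average_precision(y01, s)
        ap_neg = oracle_average_precision(1 - y01, -s)
        assert got == pytest.approx((ap_pos + ap_neg) / 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_oracle_binary(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(6, 25))
        y = np.concatenate([[0, 1], rng.integers(0, 2, size=n - 2)])
        s = rng.normal(size=n)
        # distinct scores keep the rank-based oracle exact
        s += np.linspace(0, 1e-9, n)
        got = mean_average_precision(y, np.column_stack([1 - s, s]))
        expect = (oracle_average_precision((y == 0).astype(int), 1 - s)
                  + oracle_average_precision(y, s)) / 2
        assert got == pytest.approx(expect)

    def test_random_scores_near_prevalence(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=4000)
        s = rng.normal(size=4000)
        got = mean_average_precision(y, np.column_stack([1 - s, s]))
        assert abs(got - 0.5) < 0.05


class TestAUC:
    def test_perfect_separation(self):
        assert auc_roc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_half(self):
        assert auc_roc([0, 1, 0, 1], np.ones(4)) == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(6, 30))
        y = np.concatenate([[0, 1], rng.integers(0, 2, size=n - 2)])
        s = np.round(rng.normal(size=n), 1)  # induce some ties
        assert auc_roc(y, s) == pytest.approx(oracle_auc(y, s))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        assert auc_roc(y, s) == pytest.approx(auc_roc(y, np.exp(s)))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc(np.ones(10), np.arange(10))


class TestBootstrap:
    def test_degenerate_interval(self):
        y = np.repeat([0, 1], 10)
        prob = np.eye(2)[y]
        res = bootstrap_ci(balanced_accuracy, y, prob, B=100,
                           rng=np.random.default_rng(0))
        assert res.ci_low == res.ci_high == res.estimate == 1.0

    def test_interval_brackets_estimate(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        s = y + rng.normal(0, 1, size=60)
        res = bootstrap_ci(auc_roc, y, s, B=300, rng=rng, name="auc")
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_too_small_n(self):
        with pytest.raises(ValueError):
            bootstrap_ci(auc_roc, [0, 1], [0.1, 0.9], rng=np.random.default_rng(0))


class TestPermutation:
    @staticmethod
    def _pipeline(seed):
        from sklearn.linear_model import LogisticRegression

        def fit_predict(X_train, y_train, X_test):
            m = LogisticRegression(max_iter=200, random_state=seed)
            m.fit(X_train, y_train)
            return m.predict_proba(X_test)[:, 1]
        return fit_predict

    def test_identical_pipelines_give_p_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        Xt = rng.normal(size=(20, 3))
        yt = rng.integers(0, 2, size=20)
        yt[:2] = [0, 1]
        pipe = self._pipeline(0)
        res = permutation_compare(pipe, pipe, X, y, Xt, yt, auc_roc,
                                  n_perm=50, rng=rng)
        assert res["p_value"] == 1.0
        assert res["delta_obs"] == 0.0

    def test_p_floor(self):
        res = {"p_value": 1 / 51}
        assert res["p_value"] >= 1 / (50 + 1)

    def test_small_n_perm_warns(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        y = np.tile([0, 1], 15)
        with pytest.warns(UserWarning):
            permutation_compare(self._pipeline(0), self._pipeline(1), X, y,
                                X, y, auc_roc, n_perm=10, rng=rng)


class TestSurvival:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        times = np.tile(rng.exponential(100, size=30), 2)
        events = np.ones(60, int)
        scores = np.concatenate([np.zeros(30), np.ones(30)])
        res = km_logrank(scores, scores, times, events, threshold_quantile=0.5)
        assert res["p_value"] > 0.9
        assert abs(res["statistic"]) < 0.05

    def test_eight_case_hand_table(self):
        times = np.array([5, 8, 12, 20, 6, 9, 14, 25], float)
        events = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        group = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        scores = group.astype(float)
        res = km_logrank(scores, np.array([0.5]), times, events,
                         threshold_quantile=0.5)
        expected = oracle_logrank(times, events, group)
        assert res["statistic"] == pytest.approx(expected, rel=1e-6)

    def test_km_starts_at_one(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(100, size=40)
        events = np.ones(40, int)
        scores = rng.normal(size=40)
        res = km_logrank(scores, scores, times, events)
        for curve in res["curves"].values():
            assert curve["survival"][0] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank(np.ones(10), np.zeros(10) - 5, np.arange(1, 11),
                       np.ones(10, int))

    def test_cox_sign_symmetry(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(100, size=80)
        events = rng.integers(0, 2, size=80)
        events[:5] = 1
        group = rng.integers(0, 2, size=80)
        group[:2] = [0, 1]
        a = cox_univariate(group, times, events)
        b = cox_univariate(1 - group, times, events)
        assert a["log_hr"] == pytest.approx(-b["log_hr"], rel=1e-6)

    def test_cox_recovers_known_hazard_ratio(self):
        hits = 0
        for rep in range(40):
            rng = np.random.default_rng(1000 + rep)
            group = np.repeat([0, 1], 200)
            lam = np.where(group == 1, 2.0, 1.0) / 365.0
            times = rng.exponential(1.0 / lam)
            events = np.ones(400, int)
            est = cox_univariate(group, times, events)["hr"]
            hits += 1.5 <= est <= 2.7
        assert hits >= 36  # >= 90%

    def test_cox_null_covers_zero(self):
        hits = 0
        for rep in range(40):
            rng = np.random.default_rng(2000 + rep)
            group = np.repeat([0, 1], 60)
            times = rng.exponential(365.0, size=120)
            events = np.ones(120, int)
            res = cox_univariate(group, times, events)
            hits += np.log(res["ci_low"]) <= 0.0 <= np.log(res["ci_high"])
        assert hits >= 34

    def test_cox_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate([0, 1, 0, 1], [1, 2, 3, 4], [0, 0, 0, 0])


class TestWilcoxon:
    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_small_n_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = int(rng.integers(5, 10))
        x = rng.normal(size=n)
        y = x + rng.normal(0.3, 1.0, size=n)
        assert wilcoxon_signed_rank(x, y) == pytest.approx(oracle_wilcoxon(x, y))

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        assert wilcoxon_signed_rank(x, y) == pytest.approx(wilcoxon_signed_rank(y, x))
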