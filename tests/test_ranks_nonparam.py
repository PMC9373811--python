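import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tiiclnc.survlearn import (
    SurvivalData,
    best_split,
    calibration_curve,
    concordance_index,
    km_estimate,
    logrank_scores,
    logrank_score_split,
    logrank_test,
    time_dependent_auc,
)
from .conftest import make_survival


def direct_logrank_scores(time, event):
    """Independent direct-summation oracle for the Savage/log-rank scores."""
    n = len(time)
    order = sorted(range(n), key=lambda i: (time[i], i))
    a = np.zeros(n)
    for pos_j, j in enumerate(order):
        total = 0.0
        for pos_k in range(pos_j + 1):
            k = order[pos_k]
            total += event[k] / (n - (pos_k + 1) + 1)
        a[j] = event[j] - total
    return a


class TestLogrankScores:
    def test_three_subject_hand_example(self):
        data = SurvivalData([1.0, 2.0, 3.0], [1, 1, 1], np.zeros((3, 0)))
        a = logrank_scores(data).a
        assert np.allclose(a, [2 / 3, 1 / 6, -5 / 6])

    def test_all_censored_scores_are_zero(self):
        data = SurvivalData([1.0, 2.0, 3.0], [0, 0, 0], np.zeros((3, 0)))
        assert np.allclose(logrank_scores(data).a, 0.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        time = rng.exponential(5, 10)
        event = rng.integers(0, 2, 10)
        event[0] = 1
        data = SurvivalData(time, event, np.zeros((10, 0)))
        assert np.allclose(logrank_scores(data).a,
                           direct_logrank_scores(time, event), atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(3, 25), st.integers(0, 2**31 - 1))
    def test_uncensored_scores_sum_to_zero(self, n, seed):
        rng = np.random.default_rng(seed)
        data = SurvivalData(rng.exponential(1, n), np.ones(n, int),
                            np.zeros((n, 0)))
        assert abs(logrank_scores(data).a.sum()) < 1e-10

    def test_gamma_nondecreasing_in_time_order(self):
        rng = np.random.default_rng(1)
        time = rng.exponential(1, 12).round(1)  # force some ties
        data = SurvivalData(np.maximum(time, 0.1), np.ones(12, int),
                            np.zeros((12, 0)))
        s = logrank_scores(data)
        order = np.lexsort((np.arange(12), data.time))
        assert (np.diff(s.gamma[order]) >= 0).all()


class TestSplitStatistic:
    def _data(self, n, seed):
        rng = np.random.default_rng(seed)
        time = rng.exponential(5, n)
        event = rng.integers(0, 2, n)
        event[:2] = 1
        return SurvivalData(time, event, np.zeros((n, 0)))

    def test_equal_scores_undefined(self):
        data = SurvivalData([1.0, 2.0, 3.0], [0, 0, 0], np.zeros((3, 0)))
        s = logrank_scores(data)
        with pytest.raises(ValueError, match="variance"):
            logrank_score_split(np.array([1.0, 2.0, 3.0]), s, 1.5)
        assert best_split(np.array([1.0, 2.0, 3.0]), s) is None

    def test_direct_formula_and_exhaustive_argmax(self):
        data = self._data(8, 3)
        s = logrank_scores(data)
        rng = np.random.default_rng(4)
        x = rng.normal(size=8)
        # direct formula at one cutpoint
        c = float(np.median(x))
        left = x <= c
        n1 = left.sum()
        expected = (s.a[left].sum() - n1 * s.a.mean()) / np.sqrt(
            n1 * (1 - n1 / 8) * s.a.var(ddof=1))
        assert logrank_score_split(x, s, c) == pytest.approx(expected, abs=1e-12)
        # exhaustive enumeration of every admissible cutpoint
        xs = np.sort(np.unique(x))
        cuts = (xs[:-1] + xs[1:]) / 2
        stats = [abs(logrank_score_split(x, s, ci)) for ci in cuts]
        best_c, best_s = best_split(x, s)
        assert abs(best_s) == pytest.approx(max(stats), abs=1e-12)
        assert best_c == pytest.approx(cuts[int(np.argmax(stats))])

    def test_sign_flips_when_sides_relabelled(self):
        data = self._data(10, 5)
        s = logrank_scores(data)
        rng = np.random.default_rng(6)
        x = rng.normal(size=10)
        c = 0.0
        left = logrank_score_split(x, s, c)
        # x -> -x maps {x <= c} onto {x >= -c}; with no x exactly at c the
        # complementary group statistic is the negation
        right = logrank_score_split(-x, s, -c)
        assert right == pytest.approx(-left, abs=1e-10)

    def test_empty_side_rejected(self):
        data = self._data(5, 7)
        s = logrank_scores(data)
        with pytest.raises(ValueError):
            logrank_score_split(np.arange(5.0), s, 10.0)


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km(2.5) == 1.0

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(8)
        time = rng.exponential(5, 50)
        event = rng.integers(0, 2, 50)
        km = km_estimate(time, event)
        kmf = KaplanMeierFitter().fit(time, event)
        grid = np.quantile(time, [0.1, 0.3, 0.5, 0.7, 0.9])
        ours = km(grid)
        theirs = kmf.predict(grid).to_numpy()
        assert np.allclose(ours, theirs, atol=1e-10)


class TestLogrankTest:
    def test_identical_groups_give_zero(self):
        time = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        event = np.tile([1, 1, 0, 1], 2)
        groups = np.repeat([0, 1], 4)
        chi2, p = logrank_test(time, event, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_toy_example_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        event = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        chi2, p = logrank_test(time, event, groups)
        ref = ll_logrank(time[groups == 0], time[groups == 1],
                         event[groups == 0], event[groups == 1])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])


class TestConcordance:
    def test_perfect_ordering_gives_one(self):
        time = np.arange(1.0, 11.0)
        data = SurvivalData(time, np.ones(10, int), np.zeros((10, 0)))
        assert concordance_index(-time, data) == 1.0

    def test_constant_risk_gives_half(self):
        data = make_survival(30, [0.5], seed=1)
        assert concordance_index(np.zeros(30), data) == 0.5

    def test_matches_bruteforce_pairs(self):
        data = make_survival(20, [0.7], seed=2, censor_scale=10.0)
        rng = np.random.default_rng(3)
        risk = rng.normal(size=20)
        conc = usable = 0.0
        for i in range(20):
            for j in range(20):
                if data.time[i] < data.time[j] and data.event[i] == 1:
                    usable += 1
                    if risk[i] > risk[j]:
                        conc += 1
                    elif risk[i] == risk[j]:
                        conc += 0.5
        assert concordance_index(risk, data) == pytest.approx(conc / usable)

    def test_matches_sksurv_on_distinct_times(self):
        from sksurv.metrics import concordance_index_censored

        data = make_survival(60, [0.9], seed=4, censor_scale=12.0)
        risk = data.covariates[:, 0]
        ours = concordance_index(risk, data)
        theirs = concordance_index_censored(data.event.astype(bool), data.time,
                                            risk)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_complement_under_negation(self):
        data = make_survival(25, [0.5], seed=5)
        rng = np.random.default_rng(6)
        risk = rng.normal(size=25)
        assert concordance_index(risk, data) + concordance_index(-risk, data) \
            == pytest.approx(1.0)

    def test_no_usable_pairs_rejected(self):
        data = SurvivalData([1.0, 2.0], [0, 0], np.zeros((2, 0)))
        with pytest.raises(ValueError):
            concordance_index(np.array([1.0, 2.0]), data)


class TestTimeDependentAuc:
    def test_perfect_ordering_gives_one(self):
        time = np.arange(1.0, 11.0)
        data = SurvivalData(time, np.ones(10, int), np.zeros((10, 0)))
        auc = time_dependent_auc(-time, data, [2.5, 5.5])
        assert np.allclose(auc, 1.0)

    def test_constant_risk_gives_half(self):
        data = make_survival(40, [0.5], seed=7)
        auc = time_dependent_auc(np.zeros(40), data, [np.median(data.time)])
        assert auc[0] == pytest.approx(0.5)

    def test_matches_weighted_pair_oracle(self):
        from lifelines import KaplanMeierFitter

        data = make_survival(25, [0.8], seed=8, censor_scale=8.0)
        rng = np.random.default_rng(9)
        risk = rng.normal(size=25)
        t = float(np.median(data.time))
        # oracle: censoring KM from lifelines, explicit double loop
        G = KaplanMeierFitter().fit(data.time, 1 - data.event)
        num = den_w = 0.0
        cases = np.flatnonzero((data.time <= t) & (data.event == 1))
        controls = np.flatnonzero(data.time > t)
        for i in cases:
            g = float(G.predict(data.time[i] - 1e-9))
            w = 1.0 / g
            den_w += w
            for j in controls:
                if risk[i] > risk[j]:
                    num += w
                elif risk[i] == risk[j]:
                    num += 0.5 * w
        expected = num / (den_w * len(controls))
        ours = time_dependent_auc(risk, data, [t])[0]
        assert ours == pytest.approx(expected, abs=1e-10)

    def test_undefined_horizons_reported_missing(self):
        data = make_survival(10, [0.5], seed=10)
        auc = time_dependent_auc(np.arange(10.0), data,
                                 [data.time.max() * 2])
        assert np.isnan(auc[0])


class TestCalibration:
    def test_quantile_bins_match_sort_oracle(self):
        data = make_survival(80, [1.0], seed=11)
        km_all = km_estimate(data.time, data.event)
        t = float(np.median(data.time))
        pred = np.exp(-0.05 * data.time)  # monotone in time: sortable oracle
        rows = calibration_curve(pred, data, t, n_groups=4)
        assert rows.shape[0] == 4
        assert rows[:, 2].sum() == 80
        # bins ordered by predicted survival
        assert (np.diff(rows[:, 0]) > 0).all()

    def test_truthful_predictions_lie_near_diagonal(self):
        rng = np.random.default_rng(12)
        n = 2000
        lam = 0.05 * np.exp(rng.normal(size=n))
        time = rng.exponential(1 / lam)
        data = SurvivalData(time, np.ones(n, int), np.zeros((n, 0)))
        t = float(np.median(time))
        pred = np.exp(-lam * t)  # the true survival probabilities
        rows = calibration_curve(pred, data, t, n_groups=4)
        assert np.all(np.abs(rows[:, 0] - rows[:, 1]) < 0.1)

    def test_single_group_rejected_and_degenerate_warns(self):
        data = make_survival(20, [0.5], seed=13)
        with pytest.raises(ValueError):
            calibration_curve(np.linspace(0, 1, 20), data, 1.0, n_groups=1)
        with pytest.warns(UserWarning, match="degenerate"):
            rows = calibration_curve(np.full(20, 0.5), data, 1.0, n_groups=4)
        assert rows.shape[0] == 1
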