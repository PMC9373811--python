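import numpy as np
import pandas as pd
import pytest

from tiiclnc import harness
from tiiclnc.harness import (
    ComboSpec,
    LearnerSpec,
    SignatureModel,
    build_signature,
    cohort_to_data,
    default_registry,
    enumerate_combinations,
    leaderboard,
    optimal_cutpoint,
    response_association,
    run_combo,
    select_best,
    stratify_and_test,
)
from tiiclnc.survlearn import SurvivalData, logrank_score_split, logrank_scores
from tiiclnc.exprprep import ExpressionMatrix
from tiiclnc.synthdata import SurvivalCohort
from .conftest import make_survival


def as_cohort(data, prefix="S"):
    """Wrap a SurvivalData into a SurvivalCohort for harness-level tests."""
    samples = [f"{prefix}{i:03d}" for i in range(data.n)]
    features = [f"g{j}" for j in range(data.p)]
    expr = ExpressionMatrix(
        pd.DataFrame(data.covariates.T + 10.0, index=features, columns=samples),
        "log2")
    clin = pd.DataFrame({"time": data.time, "event": data.event},
                        index=pd.Index(samples, name="sample_id"))
    return SurvivalCohort(expr, clin), features


@pytest.fixture(scope="module")
def signal_cohorts():
    train_data = make_survival(250, [1.0, -1.0, 0.8], seed=1, p=8,
                               censor_scale=25.0)
    val_data = make_survival(200, [1.0, -1.0, 0.8], seed=2, p=8,
                             censor_scale=25.0)
    train, features = as_cohort(train_data, "T")
    val, _ = as_cohort(val_data, "V")
    return train, val, features


class TestEnumeration:
    def test_single_predictor_registry(self):
        reg = {"ridge": LearnerSpec("ridge", "ridge", frozenset({"predictor"}))}
        combos = enumerate_combinations(reg)
        assert [c.id for c in combos] == ["ridge"]

    def test_two_predictors_one_selector_gives_four(self):
        reg = {
            "ridge": LearnerSpec("ridge", "ridge", frozenset({"predictor"})),
            "rsf": LearnerSpec("rsf", "rsf", frozenset({"predictor"})),
            "coxboost": LearnerSpec("coxboost", "coxboost",
                                    frozenset({"selector"})),
        }
        combos = enumerate_combinations(reg)
        assert len(combos) == 4
        assert {c.id for c in combos} == {"ridge", "rsf", "coxboost+ridge",
                                          "coxboost+rsf"}

    def test_no_same_family_composition_and_sorted(self):
        combos = enumerate_combinations(default_registry())
        for c in combos:
            if c.selector is not None:
                assert c.selector.split("[")[0] != c.predictor.split("[")[0]
        assert [c.id for c in combos] == sorted(c.id for c in combos)

    def test_registry_without_predictor_rejected(self):
        reg = {"coxboost": LearnerSpec("coxboost", "coxboost",
                                       frozenset({"selector"}))}
        with pytest.raises(ValueError):
            enumerate_combinations(reg)


class TestRunCombo:
    def test_deterministic_under_seed(self, signal_cohorts):
        train, val, features = signal_cohorts
        reg = default_registry(enet_alphas=(), stepwise_directions=())
        combo = ComboSpec("coxboost", "ridge")
        r1 = run_combo(combo, reg, train, {"v": val}, features, k=5, seed=3)
        r2 = run_combo(combo, reg, train, {"v": val}, features, k=5, seed=3)
        assert r1.cindex == r2.cindex
        assert r1.features == r2.features

    def test_signal_recovered_across_validation(self, signal_cohorts):
        train, val, features = signal_cohorts
        reg = default_registry(enet_alphas=(), stepwise_directions=())
        res = run_combo(ComboSpec("coxboost", "ridge"), reg, train, {"v": val},
                        features, k=5, seed=4)
        assert res.cindex["v"] >= 0.65
        assert set(res.features) >= {"g0", "g1", "g2"}

    def test_null_data_gives_chance_cindex(self):
        train, features = as_cohort(make_survival(200, [0.0], seed=5, p=4), "T")
        val, _ = as_cohort(make_survival(200, [0.0], seed=6, p=4), "V")
        reg = default_registry(enet_alphas=(), stepwise_directions=())
        res = run_combo(ComboSpec(None, "ridge"), reg, train, {"v": val},
                        features, k=5, seed=7)
        assert res.cindex["v"] == pytest.approx(0.5, abs=0.07)


class TestSelectBest:
    def _result(self, cid, mean, nfeat, failed=False):
        combo = ComboSpec(*cid) if isinstance(cid, tuple) else ComboSpec(None, cid)
        return harness.ComboResult(combo, {}, mean, nfeat,
                                   [f"g{i}" for i in range(nfeat)], 0,
                                   failed=failed)

    def test_single_result(self):
        r = self._result("ridge", 0.8, 5)
        assert select_best([r]) == r.combo

    def test_highest_mean_wins(self):
        a, b = self._result("a", 0.80, 5), self._result("b", 0.75, 2)
        assert select_best([a, b]).predictor == "a"

    def test_tie_broken_by_fewer_features_then_id(self):
        a, b = self._result("a", 0.8, 30), self._result("b", 0.8, 16)
        assert select_best([a, b]).predictor == "b"
        c, d = self._result("c", 0.8, 16), self._result("b", 0.8, 16)
        assert select_best([c, d]).predictor == "b"

    def test_order_invariance(self):
        results = [self._result(f"m{i}", 0.5 + 0.01 * i, i + 1)
                   for i in range(6)]
        import itertools

        picks = {select_best(list(perm)).id
                 for perm in itertools.permutations(results)}
        assert len(picks) == 1

    def test_failed_results_excluded(self):
        good = self._result("a", 0.6, 3)
        bad = self._result("b", 0.9, 0, failed=True)
        assert select_best([good, bad]).predictor == "a"
        with pytest.raises(ValueError):
            select_best([bad])


class TestOptimalCutpoint:
    def test_separated_groups_cut_between(self):
        rng = np.random.default_rng(8)
        n = 60
        scores = np.concatenate([rng.normal(0, 0.3, 30), rng.normal(5, 0.3, 30)])
        lam = np.where(scores > 2.5, 0.3, 0.05)
        time = rng.exponential(1 / lam)
        cut = optimal_cutpoint(scores, time, np.ones(n, int))
        assert 1.5 < cut < 3.5

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=10)
        time = rng.exponential(5, 10)
        event = rng.integers(0, 2, 10)
        event[:3] = 1
        cut = optimal_cutpoint(scores, time, event, minprop=0.1)
        data = SurvivalData(time, event, np.zeros((10, 0)))
        lr = logrank_scores(data)
        xs = np.sort(np.unique(scores))
        cands = [(a + b) / 2 for a, b in zip(xs, xs[1:])
                 if min(np.sum(scores <= (a + b) / 2),
                        np.sum(scores > (a + b) / 2)) >= 1]
        stats = [abs(logrank_score_split(scores, lr, c)) for c in cands]
        assert cut == pytest.approx(cands[int(np.argmax(stats))])

    def test_all_equal_scores_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutpoint(np.ones(10), np.arange(1.0, 11.0),
                             np.ones(10, int))

    def test_minprop_respected(self):
        rng = np.random.default_rng(10)
        scores = np.arange(20.0)
        time = rng.exponential(5, 20)
        cut = optimal_cutpoint(scores, time, np.ones(20, int), minprop=0.25)
        assert 5 <= np.sum(scores <= cut) <= 15


class TestStratify:
    def test_groups_swap_under_negation(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=40)
        time = rng.exponential(5, 40)
        event = np.ones(40, int)
        out = stratify_and_test(scores, 0.0, time, event)
        flipped = stratify_and_test(-scores, 0.0, time, event)
        assert np.array_equal(out["groups"] == "high", flipped["groups"] == "low")
        assert out["chi2"] == pytest.approx(flipped["chi2"], abs=1e-9)

    def test_cutpoint_outside_range_rejected(self):
        with pytest.raises(ValueError):
            stratify_and_test(np.arange(5.0), 10.0, np.arange(1.0, 6.0),
                              np.ones(5, int))


class TestResponseAssociation:
    def test_shifted_responders_detected(self):
        rng = np.random.default_rng(12)
        scores = np.concatenate([rng.normal(2, 1, 25), rng.normal(0, 1, 25)])
        response = np.repeat([1, 0], 25)
        out = response_association(scores, response)
        assert out["p"] < 0.01
        assert out["contingency"].sum() == 50

    def test_statistic_matches_bruteforce_ranks(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=12)
        response = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 0, 1])
        out = response_association(scores, response)
        u = 0.0
        for s1 in scores[response == 1]:
            for s0 in scores[response == 0]:
                u += (s1 > s0) + 0.5 * (s1 == s0)
        assert out["statistic"] == pytest.approx(u)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            response_association(np.arange(5.0), np.ones(5))


class TestSignatureModel:
    def test_build_score_roundtrip_and_missing_features(self, signal_cohorts,
                                                        tmp_path):
        train, val, features = signal_cohorts
        reg = default_registry(enet_alphas=(), stepwise_directions=())
        sig = build_signature(train, reg, features, "coxboost", "ridge",
                              k=5, seed=14)
        assert set(sig.features) >= {"g0", "g1"}
        scores = sig.score(val)
        path = tmp_path / "sig.json"
        sig.to_json(path)
        clone = SignatureModel.from_json(path)
        assert np.allclose(clone.score(val).to_numpy(), scores.to_numpy(),
                           atol=1e-12)
        # a cohort lacking a signature lncRNA is rejected with the name listed
        broken = SurvivalCohort(
            ExpressionMatrix(val.expression.data.drop(index=sig.features[0]),
                             "log2"),
            val.clinical)
        with pytest.raises(KeyError, match=sig.features[0]):
            sig.score(broken)

    def test_training_scores_reproduced(self, signal_cohorts):
        train, _, features = signal_cohorts
        reg = default_registry(enet_alphas=(), stepwise_directions=())
        sig = build_signature(train, reg, features, None, "ridge", k=5, seed=15)
        assert len(sig.features) == len(features)
        s1 = sig.score(train)
        s2 = sig.score(train)
        assert np.array_equal(s1.to_numpy(), s2.to_numpy())

    def test_batch_shift_absorbed_by_restandardization(self, signal_cohorts):
        train, val, features = signal_cohorts
        reg = default_registry(enet_alphas=(), stepwise_directions=())
        sig = build_signature(train, reg, features, None, "ridge", k=5, seed=16)
        base = sig.score(val, restandardize=True)
        shifted_expr = val.expression.data.add(
            pd.Series(np.arange(len(features), dtype=float) - 3.0,
                      index=val.expression.data.index), axis=0)
        shifted = SurvivalCohort(ExpressionMatrix(shifted_expr, "log2"),
                                 val.clinical)
        out = sig.score(shifted, restandardize=True)
        rho = pd.Series(base.to_numpy()).corr(pd.Series(out.to_numpy()),
                                              method="spearman")
        assert rho == pytest.approx(1.0, abs=1e-12)
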