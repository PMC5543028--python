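import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adbench.confidence import PredictionSet
from adbench.evaluation import (
    ADScoreVector,
    ad_ranking_score,
    auc_max,
    auc_random,
    cumulative_accuracy_curve,
    permutation_test_auc,
    predictiveness_curve,
    rank_measures,
    roc_auc,
    round_auc,
    round_half_up,
)
from conftest import make_prediction_set


def mann_whitney_oracle(scores, positive):
    """Brute-force pair counting with ties worth 1/2."""
    pos = scores[positive]
    neg = scores[~positive]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfectly_ordered(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        _, auc = roc_auc(scores, np.array([True, True, False, False]))
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        _, auc = roc_auc(np.ones(10), np.arange(10) < 4)
        assert auc == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4, dtype=bool))

    def test_matches_pair_counting_oracle(self, rng):
        scores = rng.integers(0, 10, size=50).astype(float)  # many ties
        positive = rng.random(50) < 0.4
        if positive.all() or not positive.any():
            positive[:2] = [True, False]
        _, auc = roc_auc(scores, positive)
        assert auc == pytest.approx(mann_whitney_oracle(scores, positive))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_oracle_agreement_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        scores = np.round(rng.normal(size=n), 1)
        positive = rng.random(n) < rng.uniform(0.2, 0.8)
        if positive.all() or not positive.any():
            positive[0] = ~positive[0]
        _, auc = roc_auc(scores, positive)
        assert auc == pytest.approx(mann_whitney_oracle(scores, positive))


class TestClosedForms:
    @pytest.mark.parametrize("sens,spec,expected", [
        (0.953, 0.955, 0.954),
        (0.823, 0.770, 0.797),
        (1.0, 1.0, 1.0),
    ])
    def test_auc_random(self, sens, spec, expected):
        assert round_half_up(auc_random(sens, spec), 3) == expected

    @pytest.mark.parametrize("sens,spec,expected", [
        (0.953, 0.955, 0.998),
        (0.823, 0.770, 0.959),
        (0.5, 0.5, 0.75),
    ])
    def test_auc_max(self, sens, spec, expected):
        assert round_half_up(auc_max(sens, spec), 3) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            auc_random(1.2, 0.5)
        with pytest.raises(ValueError):
            auc_max(0.5, -0.1)


class TestSignedScoreConstruction:
    def test_perfect_classifier_gives_auc_one(self, rng):
        pred, ad = make_prediction_set(tp=40, fn=0, tn=40, fp=0, ideal_ad=False)
        scores = ad_ranking_score(pred, ADScoreVector("m", "confidence", ad))
        _, auc = roc_auc(scores, pred.true_class == 1)
        assert auc == 1.0

    def test_ideal_ad_reaches_auc_max_exactly(self):
        sens, spec = 0.823, 0.770
        pred, ad = make_prediction_set(tp=823, fn=177, tn=770, fp=230, ideal_ad=True)
        scores = ad_ranking_score(pred, ADScoreVector("m", "confidence", ad))
        _, auc = roc_auc(scores, pred.true_class == 1)
        assert auc == pytest.approx(auc_max(sens, spec), abs=1e-12)
        # independent check: brute-force pair counting on the same scores
        assert auc == pytest.approx(
            mann_whitney_oracle(scores, pred.true_class == 1), abs=1e-12
        )

    def test_random_ad_averages_to_auc_random(self, rng):
        sens, spec = 0.8, 0.6
        pred, _ = make_prediction_set(tp=80, fn=20, tn=60, fp=40, ideal_ad=False)
        aucs = []
        for _ in range(200):
            ad = ADScoreVector("m", "confidence", rng.random(pred.n))
            scores = ad_ranking_score(pred, ad)
            aucs.append(roc_auc(scores, pred.true_class == 1)[1])
        assert np.mean(aucs) == pytest.approx(auc_random(sens, spec), abs=0.01)

    def test_monotone_transform_invariance(self):
        pred, ad = make_prediction_set(tp=40, fn=10, tn=35, fp=15, ideal_ad=False, seed=3)
        v1 = ADScoreVector("m", "confidence", ad)
        v2 = ADScoreVector("m", "confidence", np.exp(3 * ad) - 0.5)
        s1 = ad_ranking_score(pred, v1)
        s2 = ad_ranking_score(pred, v2)
        np.testing.assert_allclose(s1, s2)
        assert cumulative_accuracy_curve(pred, v1).ys.tolist() == \
            cumulative_accuracy_curve(pred, v2).ys.tolist()
        assert predictiveness_curve(pred, v1).ys.tolist() == \
            predictiveness_curve(pred, v2).ys.tolist()
        p1, _ = permutation_test_auc(pred, v1, B=199, seed=9)
        p2, _ = permutation_test_auc(pred, v2, B=199, seed=9)
        assert p1 == p2


class TestCumulativeAccuracy:
    def test_all_correct_is_flat_one(self):
        pred, ad = make_prediction_set(tp=20, fn=0, tn=20, fp=0, ideal_ad=False)
        ca = cumulative_accuracy_curve(pred, ADScoreVector("m", "confidence", ad))
        assert (ca.ys == 1.0).all()

    def test_hand_example(self):
        pred = PredictionSet(
            predicted_class=np.array([1, 1, 1, 1]), p_hat=np.ones(4)
        ).with_truth(np.array([1, 1, 2, 1]))
        ad = ADScoreVector("m", "confidence", np.array([0.1, 0.2, 0.3, 0.4]))
        ca = cumulative_accuracy_curve(pred, ad, quantiles=np.array([0.5, 1.0]))
        assert ca.ys.tolist() == [1.0, 0.75]

    def test_uninformative_ad_is_flat_at_overall_accuracy(self, rng):
        pred, ad = make_prediction_set(tp=700, fn=300, tn=700, fp=300,
                                       ideal_ad=False, seed=1)
        ca = cumulative_accuracy_curve(pred, ADScoreVector("m", "confidence", ad))
        acc = pred.correct.mean()
        se = np.sqrt(acc * (1 - acc) / (0.1 * pred.n))  # smallest bin count
        assert (np.abs(ca.ys - acc) <= 3 * se).all()


class TestPredictiveness:
    def test_ideal_ad_concentrates_errors_in_last_bins(self):
        pred, ad = make_prediction_set(tp=80, fn=10, tn=80, fp=10, ideal_ad=True)
        pc = predictiveness_curve(pred, ADScoreVector("m", "confidence", ad), bins=10)
        assert pc.ys[0] == 0.0
        assert pc.ys[-1] == 1.0

    def test_linear_error_probability_recovered(self, rng):
        n, bins = 5000, 10
        ad = np.sort(rng.random(n))
        p_err = 0.05 + 0.5 * np.arange(n) / n  # rises linearly in AD rank
        correct = rng.random(n) >= p_err
        pred = PredictionSet(predicted_class=np.ones(n, dtype=int), p_hat=np.ones(n))
        pred.true_class = np.where(correct, 1, 2)
        pred.correct = correct
        pc = predictiveness_curve(pred, ADScoreVector("m", "confidence", ad), bins=bins)
        for x, y in zip(pc.xs, pc.ys):
            expect = 0.05 + 0.5 * x
            se = np.sqrt(expect * (1 - expect) / (n / bins))
            assert abs(y - expect) <= 3 * se

    def test_too_many_bins_rejected(self):
        pred, ad = make_prediction_set(tp=3, fn=1, tn=3, fp=1, ideal_ad=False)
        with pytest.raises(ValueError):
            predictiveness_curve(pred, ADScoreVector("m", "confidence", ad), bins=20)


class TestPermutationTest:
    def test_ideal_ad_attains_minimal_p(self):
        pred, ad = make_prediction_set(tp=80, fn=20, tn=70, fp=30, ideal_ad=True)
        p, summary = permutation_test_auc(
            pred, ADScoreVector("m", "confidence", ad), B=199, seed=0
        )
        assert p == pytest.approx(1 / 200)
        assert summary["significant"]

    def test_null_median_matches_auc_random(self):
        pred, ad = make_prediction_set(tp=80, fn=20, tn=70, fp=30, ideal_ad=False)
        _, summary = permutation_test_auc(
            pred, ADScoreVector("m", "confidence", ad), B=999, seed=1
        )
        assert summary["null_median"] == pytest.approx(auc_random(0.8, 0.7), abs=0.01)

    def test_minimum_permutations_enforced(self):
        pred, ad = make_prediction_set(tp=5, fn=1, tn=5, fp=1, ideal_ad=False)
        with pytest.raises(ValueError):
            permutation_test_auc(pred, ADScoreVector("m", "confidence", ad), B=50)


# Rounded AUC ROC values of the random-forest block of a published AD-measure
# benchmark over ten datasets; recomputing mean ranks from these cells must
# reproduce the published mean-rank column.
RF_BLOCK = {
    "p_RFC":       [0.99, 0.93, 0.86, 0.85, 0.98, 0.59, 0.86, 0.64, 0.87, 0.90],
    "PROBSTD_RFR": [0.99, 0.93, 0.85, 0.85, 0.98, 0.59, 0.86, 0.64, 0.86, 0.90],
    "p_RFR":       [0.99, 0.93, 0.85, 0.85, 0.97, 0.59, 0.86, 0.64, 0.86, 0.90],
    "STD_RFR":     [0.99, 0.93, 0.84, 0.84, 0.98, 0.58, 0.85, 0.63, 0.85, 0.90],
    "cos_alpha":   [0.95, 0.87, 0.82, 0.82, 0.97, 0.56, 0.78, 0.61, 0.81, 0.84],
    "gamma_Euc":   [0.95, 0.86, 0.82, 0.81, 0.97, 0.55, 0.79, 0.61, 0.79, 0.85],
    "kappa_Euc":   [0.94, 0.86, 0.81, 0.80, 0.97, 0.54, 0.80, 0.61, 0.79, 0.85],
    "delta_Euc":   [0.94, 0.86, 0.84, 0.79, 0.96, 0.58, 0.78, 0.59, 0.80, 0.82],
    "delta_Tan":   [0.92, 0.85, 0.79, 0.80, 0.95, 0.55, 0.77, 0.60, 0.78, 0.83],
    "gamma_Tan":   [0.91, 0.85, 0.78, 0.80, 0.94, 0.56, 0.78, 0.58, 0.78, 0.81],
    "kappa_Tan":   [0.92, 0.85, 0.78, 0.79, 0.94, 0.57, 0.76, 0.59, 0.78, 0.81],
}

RF_BLOCK_MEAN_RANKS = {
    "p_RFC": 1.95, "PROBSTD_RFR": 2.25, "p_RFR": 2.60, "STD_RFR": 3.45,
    "cos_alpha": 6.10, "gamma_Euc": 6.50, "kappa_Euc": 7.10, "delta_Euc": 7.45,
    "delta_Tan": 9.10, "gamma_Tan": 9.70, "kappa_Tan": 9.80,
}


class TestRankMeasures:
    def test_published_rf_block_mean_ranks_reproduced(self):
        table = pd.DataFrame(RF_BLOCK).T
        ranked = rank_measures(table)
        for measure, expected in RF_BLOCK_MEAN_RANKS.items():
            assert ranked.loc[measure, "mean_rank"] == pytest.approx(expected)

    def test_distinct_aucs_rank_one_to_m(self):
        table = pd.DataFrame({"m1": [0.9], "m2": [0.8], "m3": [0.7]}).T
        ranked = rank_measures(table)
        assert ranked["mean_rank"].tolist() == [1.0, 2.0, 3.0]

    def test_full_ties_get_mean_rank(self):
        table = pd.DataFrame({"m1": [0.9, 0.8], "m2": [0.9, 0.8]}).T
        ranked = rank_measures(table)
        assert ranked["mean_rank"].tolist() == [1.5, 1.5]

    def test_missing_cell_rejected(self):
        table = pd.DataFrame({"m1": [0.9, np.nan], "m2": [0.9, 0.8]}).T
        with pytest.raises(ValueError):
            rank_measures(table)

    def test_ranks_use_rounded_values(self):
        # 0.851 vs 0.849 tie at two decimals
        table = pd.DataFrame({"m1": [0.851], "m2": [0.849]}).T
        ranked = rank_measures(table)
        assert ranked["mean_rank"].tolist() == [1.5, 1.5]


def test_round_auc_half_away_from_zero():
    assert round_auc(0.855) == 0.86
    assert round_half_up(0.7965, 3) == 0.797
    assert round_half_up(auc_max(0.823, 0.770), 3) == 0.959
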