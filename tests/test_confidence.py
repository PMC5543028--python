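import numpy as np
import pytest
from scipy.stats import kendalltau, norm
from sklearn.metrics import roc_auc_score

from adbench.confidence import (
    ClassifierSpec,
    DegenerateTrainingError,
    boosting_confidence,
    class_lag,
    collect_confidence,
    ensemble_average_probability,
    ensemble_std,
    fit_predict,
    margin_to_probability,
    platt_calibrate,
    prob_std,
    vote_fraction,
    _sigmoid,
)
from adbench.datasets import LabeledDataset


class TestElementaryMeasures:
    @pytest.mark.parametrize("y,expected", [(0.5, 0.5), (1.0, 0.0), (0.7, 0.3), (0.0, 0.0)])
    def test_class_lag(self, y, expected):
        assert class_lag(y) == pytest.approx(expected)

    def test_prob_std_examples(self):
        assert prob_std(0.5, 0.123) == pytest.approx(0.5)
        assert prob_std(0.8, 0.3) == pytest.approx(norm.cdf(-1.0))
        assert prob_std(0.8, 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_prob_std_degenerate_sigma(self):
        assert prob_std(0.8, 0.0) == 0.0
        assert prob_std(0.5, 0.0) == 0.5
        with pytest.raises(ValueError):
            prob_std(0.5, -0.1)

    def test_ensemble_average_probability(self):
        assert ensemble_average_probability([0.6, 0.8]) == pytest.approx(0.7)
        assert ensemble_average_probability([0.3] * 9) == pytest.approx(0.3)
        with pytest.raises(ValueError):
            ensemble_average_probability([])

    def test_vote_fraction(self):
        nu, c = vote_fraction([1] * 73 + [2] * 27)
        assert (nu, c) == (pytest.approx(0.73), 1)
        assert vote_fraction([2, 2, 2]) == (1.0, 2)
        assert vote_fraction([1, 2]) == (0.5, 1)  # exact tie -> class 1

    def test_average_probability_is_vote_fraction_on_binary_members(self, rng):
        """Hard 0/1 member probabilities make p-bar the vote fraction exactly."""
        votes = rng.integers(1, 3, size=101)
        member_p1 = (votes == 1).astype(float)
        nu, c = vote_fraction(votes)
        pbar1 = ensemble_average_probability(member_p1)
        assert max(pbar1, 1 - pbar1) == pytest.approx(nu)

    def test_ensemble_std(self, rng):
        assert ensemble_std([0.4, 0.4, 0.4]) == pytest.approx(0.0, abs=1e-15)
        assert ensemble_std([0.0, 1.0]) == pytest.approx(np.sqrt(0.5))
        out = rng.normal(size=8)
        assert ensemble_std(3 * out) == pytest.approx(3 * ensemble_std(out))
        with pytest.raises(ValueError):
            ensemble_std([0.5])

    def test_boosting_confidence(self):
        f, F = boosting_confidence([0.3, 1.7], [1, 1])
        assert f == pytest.approx(1.0)
        f, F = boosting_confidence([2.0, 1.0], [1, -1])
        assert f == pytest.approx(1 / 3)
        assert F == pytest.approx(1.0)
        f_neg, F_neg = boosting_confidence([2.0, 1.0], [-1, 1])
        assert f_neg == pytest.approx(-f)
        assert abs(f_neg) == pytest.approx(abs(f))  # AD value 1-|f| unchanged

    def test_margin_to_probability(self):
        assert margin_to_probability(0.0) == 0.5
        assert margin_to_probability(1.0) == pytest.approx(1 / (1 + np.exp(-2)))
        for F in (-2.0, -0.3, 0.7):
            assert margin_to_probability(F) + margin_to_probability(-F) == pytest.approx(1.0)


class TestOrientation:
    """Moving a prediction toward the decision boundary never lowers its AD value."""

    def test_class_lag_monotone_toward_half(self):
        ys = np.linspace(1.0, 0.5, 20)
        vals = [class_lag(y) for y in ys]
        assert (np.diff(vals) >= 0).all()

    def test_prob_std_monotone_toward_half(self):
        ys = np.linspace(0.99, 0.5, 20)
        vals = [prob_std(y, 0.2) for y in ys]
        assert (np.diff(vals) >= 0).all()

    def test_margin_error_monotone_in_abs_margin(self):
        fs = np.linspace(1.0, 0.0, 20)
        assert (np.diff(1 - np.abs(fs)) >= 0).all()


class TestPlatt:
    def test_parameter_recovery(self, rng):
        w0_true, w1_true = -0.7, 2.3
        n = 8000
        d = rng.normal(size=n)
        p = _sigmoid(w0_true + w1_true * d)
        y = (rng.random(n) < p).astype(int)
        w0, w1 = platt_calibrate(d, y)
        assert w0 == pytest.approx(w0_true, rel=0.10, abs=0.05)
        assert w1 == pytest.approx(w1_true, rel=0.10)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateTrainingError):
            platt_calibrate([0.1, 0.2, 0.3], [1, 1, 1])

    def test_calibration_is_rank_preserving(self, separable_dataset, intermediate_dataset):
        ds = intermediate_dataset
        spec = ClassifierSpec(family="SVM", seed=0)
        train = ds.subset(np.arange(0, ds.n, 2))
        test = ds.subset(np.arange(1, ds.n, 2))
        pred = fit_predict(spec, train, test.X)
        tau, _ = kendalltau(pred.decision_value, pred.p1)
        assert abs(tau) == pytest.approx(1.0)
        # AUC from calibrated probabilities == AUC from (oriented) decision values
        auc_p = roc_auc_score(test.y == 1, pred.p1)
        sign = np.sign(tau)
        auc_d = roc_auc_score(test.y == 1, sign * pred.decision_value)
        assert auc_p == pytest.approx(auc_d)


class TestFitPredict:
    def test_knn_probability_is_neighbor_fraction(self):
        X = np.array([[0.0], [0.1], [0.2], [0.3], [0.4], [5.0], [6.0]])
        y = np.array([1, 1, 1, 2, 2, 2, 2])
        pred = fit_predict(ClassifierSpec(family="kNN", k=5), LabeledDataset(X=X, y=y), np.array([[0.0]]))
        assert pred.predicted_class[0] == 1
        assert pred.p_hat[0] == pytest.approx(0.6)

    def test_regression_threshold_rule(self):
        from adbench.confidence import _regression_predictions

        pred, p_hat = _regression_predictions(np.array([0.49, 0.51, 0.5]))
        assert pred.tolist() == [2, 1, 2]
        np.testing.assert_allclose(p_hat, [0.51, 0.51, 0.5])

    def test_one_class_training_rejected(self):
        ds = LabeledDataset(X=np.random.default_rng(0).normal(size=(10, 2)),
                            y=np.ones(10, dtype=int))
        with pytest.raises(DegenerateTrainingError):
            fit_predict(ClassifierSpec(family="LDA"), ds, np.zeros((1, 2)))


@pytest.fixture(scope="module")
def split(intermediate_dataset):
    ds = intermediate_dataset
    return ds.subset(np.arange(0, ds.n, 2)), ds.subset(np.arange(1, ds.n, 2))


class TestCollectConfidence:
    def test_class_lag_equals_one_minus_knn_probability(self, split):
        train, test = split
        spec = ClassifierSpec(family="kNN", k=5)
        pred = fit_predict(spec, train, test.X)
        # CLASS-LAG applied to p_hat-as-y_hat reproduces 1 - p_hat bit-exactly
        lag = np.minimum(np.abs(pred.p_hat), np.abs(1.0 - pred.p_hat))
        assert np.array_equal(lag, 1.0 - pred.p_hat)

    def test_regression_measures_bounded(self, split):
        train, test = split
        spec = ClassifierSpec(family="RF", mode="regression", n_tree=50)
        pred = fit_predict(spec, train, test.X)
        conf = collect_confidence(pred, spec)
        assert set(conf) == {"class_lag", "std", "prob_std"}
        assert (conf["class_lag"] <= 0.5 + 1e-12).all()
        assert (conf["prob_std"] <= 0.5 + 1e-12).all()
        for v in conf.values():
            assert (v >= 0).all()

    def test_mb_measures(self, split):
        train, test = split
        spec = ClassifierSpec(family="MB", n_boost=20, n_bag=3)
        pred = fit_predict(spec, train, test.X)
        conf = collect_confidence(pred, spec)
        assert set(conf) == {"margin_error", "vote_error"}
        assert ((pred.f_bar >= -1) & (pred.f_bar <= 1)).all()
        assert ((conf["vote_error"] >= 0) & (conf["vote_error"] <= 0.5 + 1e-12)).all()

    def test_unsupported_mode_raises(self):
        with pytest.raises(ValueError):
            ClassifierSpec(family="kNN", mode="regression")

    def test_spec_round_trips_through_mapping(self):
        spec = ClassifierSpec(family="RF", mode="regression", n_tree=77, seed=5)
        assert ClassifierSpec.from_mapping(spec.to_mapping()) == spec
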