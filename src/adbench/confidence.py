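"""Classifier adapters exposing confidence-based applicability-domain measures.

Six classifier families are wrapped behind one interface: random forests
(RF), ensembles of feedforward neural networks (NN), support vector machines
(SVM), bagged AdaBoost.M1 decision stumps ("multiple boosting", MB),
k-nearest neighbors (kNN) and linear discriminant analysis (LDA).  RF, NN
and SVM also run in regression mode against the numeric targets y=1 (class
1) / y=0 (class 2), where the fitted regression function estimates
p(1|x) and class assignment thresholds at 0.5.

From each fitted family the applicable confidence measures are extracted and
oriented as error probabilities (larger = less reliable):

* ``p_hat_error`` = 1 - p_hat (classification-mode class-probability estimate),
* ``class_lag``   = min(|y_hat|, |1-y_hat|) (regression mode),
* ``std``         = ensemble standard deviation of member predictions,
* ``prob_std``    = normal tail area beyond the 0.5 decision value,
* ``vote_error``  = 1 - vote fraction of the majority class,
* ``margin_error``= 1 - |mean normalized boosting margin|.

Learning itself is delegated to scikit-learn; this module owns the measure
definitions, orientation and bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier

from adbench.datasets import LabeledDataset

FAMILIES = ("RF", "NN", "SVM", "MB", "kNN", "LDA")
REGRESSION_FAMILIES = ("RF", "NN", "SVM")


class DegenerateTrainingError(ValueError):
    """Training data contains a single class."""


class UnsupportedMeasureError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierSpec:
    """Family, mode and frozen hyperparameters of one classifier run.

    Defaults follow common library defaults: RF with 500 trees; a
    five-membered ensemble of one-hidden-layer networks (softmax outputs in
    classification, squared-error loss in regression); RBF-kernel SVM with
    C=1 and gamma=1/p; bagging (10 bootstrap replicates) of AdaBoost.M1 with
    100 decision stumps; kNN with k=5; plain LDA.  ``params`` passes extra
    keyword arguments straight to the underlying scikit-learn estimator.
    """

    family: str
    mode: str = "classification"
    n_tree: int = 500
    n_members: int = 5
    n_boost: int = 100
    n_bag: int = 10
    k: int = 5
    hidden_units: int = 16
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.mode not in ("classification", "regression"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "regression" and self.family not in REGRESSION_FAMILIES:
            raise ValueError(f"{self.family} has no regression mode")

    @property
    def label(self) -> str:
        suffix = {"classification": "C", "regression": "R"}[self.mode]
        return f"{self.family}{suffix}" if self.family in REGRESSION_FAMILIES else self.family

    def to_mapping(self) -> dict:
        """Plain key/value form for config files."""
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ClassifierSpec":
        return cls(**mapping)


@dataclass
class PredictionSet:
    """Per-object predictions and the raw quantities the AD measures need.

    ``p1`` is the estimated probability of class 1 (classification mode) and
    ``y_hat`` the regression output (regression mode; also an estimate of
    p(1|x)).  ``p_hat`` is the probability of the *predicted* class, hence
    >= 0.5.  Ensemble members contribute ``member_outputs`` (n x m) and
    ``sigma_hat``; SVMs and boosting contribute ``decision_value``; boosting
    additionally the mean normalized margin ``f_bar`` and vote fraction
    ``nu_hat``.
    """

    predicted_class: np.ndarray
    p_hat: np.ndarray
    p1: Optional[np.ndarray] = None
    y_hat: Optional[np.ndarray] = None
    member_outputs: Optional[np.ndarray] = None
    sigma_hat: Optional[np.ndarray] = None
    decision_value: Optional[np.ndarray] = None
    f_bar: Optional[np.ndarray] = None
    nu_hat: Optional[np.ndarray] = None
    true_class: Optional[np.ndarray] = None
    correct: Optional[np.ndarray] = None

    def with_truth(self, true_class: np.ndarray) -> "PredictionSet":
        self.true_class = np.asarray(true_class, dtype=int)
        self.correct = self.predicted_class == self.true_class
        return self

    @property
    def n(self) -> int:
        return len(self.predicted_class)


#: ConfidenceScores: map from measure name to per-object AD values
ConfidenceScores = Dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# elementary measure definitions


def ensemble_average_probability(member_probs: Sequence[float]) -> float:
    """Arithmetic mean of per-member probabilities of class 1 (p-bar)."""
    member_probs = np.asarray(member_probs, dtype=float)
    if member_probs.size == 0:
        raise ValueError("empty ensemble")
    if ((member_probs < 0) | (member_probs > 1)).any():
        raise ValueError("member probabilities must lie in [0, 1]")
    return float(member_probs.mean())


def vote_fraction(member_classes: Sequence[int]) -> Tuple[float, int]:
    """(nu_hat, predicted_class) from ensemble hard votes; 50/50 ties -> class 1."""
    votes = np.asarray(member_classes, dtype=int)
    if votes.size == 0:
        raise ValueError("empty ensemble")
    frac1 = float(np.mean(votes == 1))
    if frac1 >= 0.5:
        return frac1, 1
    return 1.0 - frac1, 2


def class_lag(y_hat: float) -> float:
    """min(|0 - y_hat|, |1 - y_hat|): the smaller estimated error probability."""
    return float(np.minimum(np.abs(y_hat), np.abs(1.0 - y_hat)))


def ensemble_std(member_outputs: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator) of ensemble member outputs."""
    out = np.asarray(member_outputs, dtype=float)
    if out.size < 2:
        raise ValueError("STD needs at least 2 ensemble members")
    return float(out.std(ddof=1))


def prob_std(y_hat: float, sigma_hat: float) -> float:
    """Normal tail area beyond the 0.5 decision value for the alternative class.

    min of the two tails of N(y_hat, sigma_hat) about 0.5, i.e.
    Phi(-|y_hat - 0.5| / sigma_hat).  At sigma_hat = 0 the limit values are
    used (0 off the boundary, 0.5 on it).
    """
    if sigma_hat < 0:
        raise ValueError("sigma_hat must be nonnegative")
    dev = abs(float(y_hat) - 0.5)
    if sigma_hat == 0.0:
        return 0.5 if dev == 0.0 else 0.0
    return float(norm.cdf(-dev / sigma_hat))


def boosting_confidence(
    alphas: Sequence[float], member_outputs: Sequence[int]
) -> Tuple[float, float]:
    """(f, F) of one boosted ensemble: normalized and raw weighted votes.

    ``F = sum(alpha_i * h_i)`` with h_i in {-1, +1}; ``f`` uses weights
    normalized to sum 1, so f lies in [-1, 1] and |f| is the absolute margin.
    The predicted label is sign(F).
    """
    a = np.asarray(alphas, dtype=float)
    h = np.asarray(member_outputs, dtype=float)
    if a.shape != h.shape:
        raise ValueError("alphas and member outputs must have equal length")
    total = a.sum()
    if total <= 0:
        raise ValueError("weights must have positive sum")
    F = float(a @ h)
    return F / total, F


def margin_to_probability(F):
    """Logistic transform of the unnormalized boosting score: 1/(1+exp(-2F))."""
    out = 1.0 / (1.0 + np.exp(-2.0 * np.asarray(F, dtype=float)))
    return float(out) if out.ndim == 0 else out


def platt_calibrate(
    decision_values: Sequence[float], labels: Sequence[int]
) -> Tuple[float, float]:
    """Platt scaling: logistic fit of p(y=1|decval) = sigm(w0 + w1*decval).

    ``labels`` are 0/1 with 1 for class 1.  Decision values should come from
    a cross-validation of the training set so the sigmoid is not fitted on
    resubstitution scores.  Calibration is monotone and therefore leaves
    every rank-based benchmark criterion unchanged.
    """
    d = np.asarray(decision_values, dtype=float).reshape(-1, 1)
    t = np.asarray(labels, dtype=int)
    if len(np.unique(t)) < 2:
        raise DegenerateTrainingError("Platt calibration needs both classes")
    # effectively unpenalized fit (Platt's maximum-likelihood sigmoid)
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    lr.fit(d, t)
    return float(lr.intercept_[0]), float(lr.coef_[0, 0])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# family adapters


def _check_train(train: LabeledDataset) -> None:
    if len(np.unique(train.y)) < 2:
        raise DegenerateTrainingError("training data contains a single class")


def _p1_to_predictions(p1: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    # probability ties at exactly 0.5 resolve to class 1
    pred = np.where(p1 >= 0.5, 1, 2)
    return pred, np.where(pred == 1, p1, 1.0 - p1)


def _regression_predictions(y_hat: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    # class 1 iff y_hat > 1/2 ("otherwise" -> class 2)
    pred = np.where(y_hat > 0.5, 1, 2)
    return pred, np.where(pred == 1, y_hat, 1.0 - y_hat)


def _proba_class1(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    col = int(np.flatnonzero(model.classes_ == 1)[0])
    return proba[:, col]


def _fit_rf(spec: ClassifierSpec, train: LabeledDataset, test_X: np.ndarray) -> PredictionSet:
    if spec.mode == "classification":
        model = RandomForestClassifier(
            n_estimators=spec.n_tree, random_state=spec.seed, **spec.params
        )
        model.fit(train.X, train.y)
        p1 = _proba_class1(model, test_X)  # unweighted average of per-tree leaf fractions
        pred, p_hat = _p1_to_predictions(p1)
        return PredictionSet(predicted_class=pred, p_hat=p_hat, p1=p1)
    model = RandomForestRegressor(
        n_estimators=spec.n_tree, random_state=spec.seed, **spec.params
    )
    model.fit(train.X, (train.y == 1).astype(float))
    members = np.column_stack([t.predict(test_X) for t in model.estimators_])
    y_hat = members.mean(axis=1)
    sigma = members.std(axis=1, ddof=1)
    pred, p_hat = _regression_predictions(y_hat)
    return PredictionSet(
        predicted_class=pred, p_hat=p_hat, y_hat=y_hat,
        member_outputs=members, sigma_hat=sigma,
    )


def _fit_nn(spec: ClassifierSpec, train: LabeledDataset, test_X: np.ndarray) -> PredictionSet:
    members = []
    for i in range(spec.n_members):
        if spec.mode == "classification":
            net = MLPClassifier(
                hidden_layer_sizes=(spec.hidden_units,), solver="lbfgs",
                max_iter=500, random_state=spec.seed + i, **spec.params,
            )
            net.fit(train.X, train.y)
            members.append(_proba_class1(net, test_X))
        else:
            net = MLPRegressor(
                hidden_layer_sizes=(spec.hidden_units,), solver="lbfgs",
                max_iter=500, random_state=spec.seed + i, **spec.params,
            )
            net.fit(train.X, (train.y == 1).astype(float))
            # a linear output node is unbounded; clip to the probability scale
            members.append(np.clip(net.predict(test_X), 0.0, 1.0))
    M = np.column_stack(members)
    mean_out = M.mean(axis=1)
    sigma = M.std(axis=1, ddof=1)
    if spec.mode == "classification":
        pred, p_hat = _p1_to_predictions(mean_out)
        return PredictionSet(
            predicted_class=pred, p_hat=p_hat, p1=mean_out,
            member_outputs=M, sigma_hat=sigma,
        )
    pred, p_hat = _regression_predictions(mean_out)
    return PredictionSet(
        predicted_class=pred, p_hat=p_hat, y_hat=mean_out,
        member_outputs=M, sigma_hat=sigma,
    )


def _fit_svm(spec: ClassifierSpec, train: LabeledDataset, test_X: np.ndarray) -> PredictionSet:
    gamma = 1.0 / train.p
    if spec.mode == "classification":
        model = SVC(kernel="rbf", C=1.0, gamma=gamma, random_state=spec.seed, **spec.params)
        model.fit(train.X, train.y)
        decval = model.decision_function(test_X)
        # Platt scaling on fivefold-CV decision values of the training set
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=spec.seed)
        cv_dec = cross_val_predict(model, train.X, train.y, cv=cv, method="decision_function")
        w0, w1 = platt_calibrate(cv_dec, (train.y == 1).astype(int))
        p1 = _sigmoid(w0 + w1 * decval)
        pred, p_hat = _p1_to_predictions(p1)
        return PredictionSet(
            predicted_class=pred, p_hat=p_hat, p1=p1, decision_value=decval
        )
    model = SVR(kernel="rbf", C=1.0, gamma=gamma, **spec.params)
    model.fit(train.X, (train.y == 1).astype(float))
    y_hat = np.clip(model.predict(test_X), 0.0, 1.0)
    pred, p_hat = _regression_predictions(y_hat)
    return PredictionSet(predicted_class=pred, p_hat=p_hat, y_hat=y_hat)


def _fit_mb(spec: ClassifierSpec, train: LabeledDataset, test_X: np.ndarray) -> PredictionSet:
    rng = np.random.default_rng(spec.seed)
    n = train.n
    f_vals = np.zeros((test_X.shape[0], spec.n_bag))
    F_vals = np.zeros_like(f_vals)
    stump_votes_1 = np.zeros(test_X.shape[0])  # unweighted class-1 votes over all stumps
    n_stumps = 0
    for b in range(spec.n_bag):
        while True:  # bootstrap must contain both classes
            idx = rng.integers(0, n, size=n)
            if len(np.unique(train.y[idx])) == 2:
                break
        booster = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=spec.n_boost,
            random_state=spec.seed + b,
            **spec.params,
        )
        booster.fit(train.X[idx], train.y[idx])
        alphas = booster.estimator_weights_[: len(booster.estimators_)]
        H = np.column_stack(
            [np.where(est.predict(test_X) == 1, 1.0, -1.0) for est in booster.estimators_]
        )
        F = H @ alphas
        f_vals[:, b] = F / alphas.sum()
        F_vals[:, b] = F
        stump_votes_1 += (H == 1.0).sum(axis=1)
        n_stumps += H.shape[1]
    f_bar = f_vals.mean(axis=1)
    F_bar = F_vals.mean(axis=1)
    frac1 = stump_votes_1 / n_stumps
    pred = np.where(f_bar >= 0.0, 1, 2)  # sign of the decision function; ties -> 1
    nu_hat = np.maximum(frac1, 1.0 - frac1)  # majority-vote fraction
    p1 = margin_to_probability(F_bar)
    p_hat = np.where(pred == 1, p1, 1.0 - p1)
    return PredictionSet(
        predicted_class=pred, p_hat=np.asarray(p_hat, dtype=float), p1=np.asarray(p1),
        decision_value=F_bar, f_bar=f_bar, nu_hat=np.asarray(nu_hat, dtype=float),
        member_outputs=f_vals,
    )


def _fit_knn(spec: ClassifierSpec, train: LabeledDataset, test_X: np.ndarray) -> PredictionSet:
    model = KNeighborsClassifier(n_neighbors=spec.k, **spec.params)
    model.fit(train.X, train.y)
    p1 = _proba_class1(model, test_X)
    pred, p_hat = _p1_to_predictions(p1)
    return PredictionSet(predicted_class=pred, p_hat=p_hat, p1=p1)


def _fit_lda(spec: ClassifierSpec, train: LabeledDataset, test_X: np.ndarray) -> PredictionSet:
    model = LinearDiscriminantAnalysis(**spec.params)
    model.fit(train.X, train.y)
    p1 = _proba_class1(model, test_X)
    pred, p_hat = _p1_to_predictions(p1)
    return PredictionSet(predicted_class=pred, p_hat=p_hat, p1=p1)


_FITTERS = {
    "RF": _fit_rf,
    "NN": _fit_nn,
    "SVM": _fit_svm,
    "MB": _fit_mb,
    "kNN": _fit_knn,
    "LDA": _fit_lda,
}


def fit_predict(
    spec: ClassifierSpec, train: LabeledDataset, test_X: np.ndarray
) -> PredictionSet:
    """Fit the requested family on ``train`` and predict ``test_X``.

    Fills every :class:`PredictionSet` field the family supports.
    """
    _check_train(train)
    test_X = np.asarray(test_X, dtype=float)
    if test_X.shape[1] != train.p:
        raise ValueError("test dimension does not match training data")
    return _FITTERS[spec.family](spec, train, test_X)


# ---------------------------------------------------------------------------
# measure collection

#: measures defined for each (family, mode) combination
FAMILY_MEASURES = {
    ("RF", "classification"): ("p_hat_error",),
    ("RF", "regression"): ("class_lag", "std", "prob_std"),
    ("NN", "classification"): ("p_hat_error",),
    ("NN", "regression"): ("class_lag", "std", "prob_std"),
    ("SVM", "classification"): ("p_hat_error",),
    ("SVM", "regression"): ("class_lag",),
    ("MB", "classification"): ("margin_error", "vote_error"),
    ("kNN", "classification"): ("p_hat_error",),
    ("LDA", "classification"): ("p_hat_error",),
}


def collect_confidence(pred: PredictionSet, spec: ClassifierSpec) -> ConfidenceScores:
    """Every family-applicable confidence measure, oriented larger = less reliable."""
    names = FAMILY_MEASURES.get((spec.family, spec.mode))
    if names is None:
        raise UnsupportedMeasureError(f"no measures for {spec.family}/{spec.mode}")
    out: ConfidenceScores = {}
    for name in names:
        if name == "p_hat_error":
            out[name] = 1.0 - pred.p_hat
        elif name == "class_lag":
            out[name] = np.minimum(np.abs(pred.y_hat), np.abs(1.0 - pred.y_hat))
        elif name == "std":
            out[name] = pred.sigma_hat.copy()
        elif name == "prob_std":
            out[name] = np.array(
                [prob_std(y, s) for y, s in zip(pred.y_hat, pred.sigma_hat)]
            )
        elif name == "vote_error":
            out[name] = 1.0 - pred.nu_hat
        elif name == "margin_error":
            out[name] = 1.0 - np.abs(pred.f_bar)
    return out
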