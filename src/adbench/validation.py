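"""Fivefold cross-validation, random-undersampling CV and confusion metrics.

Plain K-fold CV pools one out-of-fold prediction per object, so the pooled
prediction error is an unbiased estimate for a training-set size of
(K-1)/K of the data.  When the minority class falls below 40% of the data,
random-undersampling CV (RUS CV) balances each *training* partition to 1:1
by subsampling the majority class before fitting — the test partitions are
never touched — and averages per-object probabilities over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional
import warnings

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from adbench.confidence import (
    ClassifierSpec,
    PredictionSet,
    fit_predict,
)
from adbench.datasets import LabeledDataset

RUS_MINORITY_THRESHOLD = 0.4


class DegenerateFoldError(ValueError):
    """A training fold is missing a class entirely."""


@dataclass
class FoldAssignment:
    """Partition of n objects into K folds (sizes differing by at most 1)."""

    fold_id: np.ndarray  # per object, in 1..K
    K: int
    seed: int

    def __post_init__(self) -> None:
        self.fold_id = np.asarray(self.fold_id, dtype=int)
        counts = np.bincount(self.fold_id, minlength=self.K + 1)[1:]
        if counts.sum() != len(self.fold_id) or counts.max() - counts.min() > 1:
            raise ValueError("fold ids must partition the objects near-evenly")

    @property
    def n(self) -> int:
        return len(self.fold_id)

    def test_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id == k)

    def train_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id != k)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"object": np.arange(self.n), "fold": self.fold_id}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = -1) -> "FoldAssignment":
        df = pd.read_csv(path)
        fold = df["fold"].to_numpy(dtype=int)[np.argsort(df["object"].to_numpy())]
        return cls(fold_id=fold, K=int(fold.max()), seed=seed)


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sens(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def spec(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / self.n


def kfold_split(
    n: int, K: int, seed: int, labels: Optional[np.ndarray] = None
) -> FoldAssignment:
    """Random K-fold partition; stratified on ``labels`` when supplied."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if n < K:
        raise ValueError(f"cannot split {n} objects into {K} folds")
    fold = np.empty(n, dtype=int)
    if labels is None:
        splitter = KFold(n_splits=K, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n))
    else:
        splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n), np.asarray(labels))
    for k, (_, test_idx) in enumerate(split, start=1):
        fold[test_idx] = k
    return FoldAssignment(fold_id=fold, K=K, seed=seed)


def _merge_pooled(parts: dict[int, PredictionSet], folds: FoldAssignment) -> PredictionSet:
    """Reassemble per-fold PredictionSets into object order."""
    n = folds.n

    def gather(attr):
        sample = getattr(parts[1], attr)
        if sample is None:
            return None
        shape = (n,) if sample.ndim == 1 else (n, sample.shape[1])
        out = np.empty(shape, dtype=float)
        for k, ps in parts.items():
            out[folds.test_indices(k)] = getattr(ps, attr)
        return out

    merged = PredictionSet(
        predicted_class=gather("predicted_class").astype(int),
        p_hat=gather("p_hat"),
        p1=gather("p1"),
        y_hat=gather("y_hat"),
        member_outputs=gather("member_outputs"),
        sigma_hat=gather("sigma_hat"),
        decision_value=gather("decision_value"),
        f_bar=gather("f_bar"),
        nu_hat=gather("nu_hat"),
    )
    return merged


def _check_fold_classes(y_train: np.ndarray) -> None:
    if len(np.unique(y_train)) < 2:
        raise DegenerateFoldError("a training fold is missing a class")


def run_cv(
    ds: LabeledDataset, spec: ClassifierSpec, folds: FoldAssignment
) -> PredictionSet:
    """Pooled out-of-fold predictions: each object predicted once by a model
    that never saw it."""
    if folds.n != ds.n:
        raise ValueError("fold assignment does not match the dataset")
    parts: dict[int, PredictionSet] = {}
    for k in range(1, folds.K + 1):
        tr = folds.train_indices(k)
        te = folds.test_indices(k)
        _check_fold_classes(ds.y[tr])
        parts[k] = fit_predict(spec, ds.subset(tr), ds.X[te])
    return _merge_pooled(parts, folds).with_truth(ds.y)


def _undersample_balanced(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a 1:1 subsample (all minority objects, matched majority draw)."""
    idx1 = np.flatnonzero(y == 1)
    idx2 = np.flatnonzero(y == 2)
    minority, majority = (idx1, idx2) if len(idx1) <= len(idx2) else (idx2, idx1)
    if len(minority) < 2:
        raise ValueError("undersampled training fold smaller than 2 per class")
    keep = rng.choice(majority, size=len(minority), replace=False)
    return np.sort(np.concatenate([minority, keep]))


def rus_cv(
    ds: LabeledDataset,
    spec: ClassifierSpec,
    K: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> PredictionSet:
    """Random-undersampling CV for imbalanced data.

    In every repeat the training partition of each fold is undersampled to
    exactly balanced classes before fitting; the test partition is left
    untouched.  Per-object probabilities (and the other raw confidence
    quantities) are averaged over repeats on the probability scale, and the
    predicted class is derived from the averaged probability.
    """
    y1_frac = float(np.mean(ds.y == 1))
    if min(y1_frac, 1 - y1_frac) >= RUS_MINORITY_THRESHOLD:
        warnings.warn(
            "RUS CV requested although the minority class is >= 40% of the data",
            stacklevel=2,
        )
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    folds = kfold_split(ds.n, K, seed=seed, labels=ds.y)
    pooled: list[PredictionSet] = []
    for _ in range(repeats):
        parts: dict[int, PredictionSet] = {}
        for k in range(1, K + 1):
            tr = folds.train_indices(k)
            te = folds.test_indices(k)
            _check_fold_classes(ds.y[tr])
            sub = tr[_undersample_balanced(ds.y[tr], rng)]
            parts[k] = fit_predict(spec, ds.subset(sub), ds.X[te])
        pooled.append(_merge_pooled(parts, folds))

    def avg(attr):
        vals = [getattr(ps, attr) for ps in pooled]
        if vals[0] is None:
            return None
        return np.mean(np.stack(vals), axis=0)

    p1 = avg("p1")
    y_hat = avg("y_hat")
    sigma = avg("sigma_hat")
    f_bar = avg("f_bar")
    nu = avg("nu_hat")
    if spec.mode == "regression":
        pred = np.where(y_hat > 0.5, 1, 2)
        p_hat = np.where(pred == 1, y_hat, 1.0 - y_hat)
    elif spec.family == "MB":
        pred = np.where(f_bar >= 0.0, 1, 2)
        p_hat = np.where(pred == 1, p1, 1.0 - p1)
        nu = np.maximum(nu, 1.0 - nu)
    else:
        pred = np.where(p1 >= 0.5, 1, 2)
        p_hat = np.where(pred == 1, p1, 1.0 - p1)
    merged = PredictionSet(
        predicted_class=pred.astype(int), p_hat=p_hat, p1=p1, y_hat=y_hat,
        member_outputs=avg("member_outputs"), sigma_hat=sigma,
        decision_value=avg("decision_value"), f_bar=f_bar, nu_hat=nu,
    )
    return merged.with_truth(ds.y)


def confusion_metrics(pred: PredictionSet) -> ConfusionMetrics:
    """Counts and ratios with class 1 as positive.

    If one true class is absent the corresponding rate is NaN (flagged with a
    warning) rather than raising.
    """
    if pred.true_class is None:
        raise ValueError("true_class required for confusion metrics")
    t = pred.true_class
    p = pred.predicted_class
    cm = ConfusionMetrics(
        tp=int(np.sum((t == 1) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 2))),
        tn=int(np.sum((t == 2) & (p == 2))),
        fp=int(np.sum((t == 2) & (p == 1))),
    )
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        warnings.warn("one true class absent: sensitivity or specificity undefined",
                      stacklevel=2)
    return cm
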