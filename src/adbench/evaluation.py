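"""Benchmarking layer: signed-score ROC for AD measures, curves, permutation
significance and rank aggregation.

An AD measure orders predictions from reliable to unreliable but carries no
class information of its own, so a plain ROC against the true class would be
meaningless.  The benchmark therefore builds a *signed reliability score*:
the AD values are rank-normalized to a reliability r in (0, 1) (larger =
more reliable), and the score is +r for objects predicted class 1 and -r
for objects predicted class 2.  A ROC of this score against the true class
(class 1 positive) then rewards measures that push confident correct
predictions to the extremes and errors toward the center of the ranking.

The construction is pinned down by two closed forms that follow from simple
geometric arguments: a random ranking of the prediction errors yields
``AUC_random = 0.5*(Sens + Spec)`` (the median of the permutation-null
distribution), and an ideal measure — every error ranked least reliable
within its predicted class — yields ``AUC_max = 1 - (1-Sens)*(1-Spec)``.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from adbench.confidence import PredictionSet


@dataclass
class ADScoreVector:
    """One AD measure's per-object values, oriented larger = less reliable."""

    name: str
    category: str  # "novelty" | "confidence"
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.category not in ("novelty", "confidence"):
            raise ValueError(f"unknown category {self.category!r}")
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class CurveData:
    """Points of a ROC / cumulative-accuracy / predictiveness curve.

    ``thresholds`` carries the AD value that realizes each quantile point
    (CA and predictiveness curves), so reject thresholds can be resolved
    back to the AD scale.
    """

    kind: str  # "roc" | "cumulative_accuracy" | "predictiveness"
    xs: np.ndarray
    ys: np.ndarray
    n: int
    auc: Optional[float] = None
    thresholds: Optional[np.ndarray] = None


def ad_ranking_score(pred: PredictionSet, ad: ADScoreVector) -> np.ndarray:
    """Signed reliability score of each object.

    Reliability ``r_i = 1 - rank(ad_i)/(n+1)`` (mean rank on ties, so r lies
    strictly inside (0, 1)); the signed score is ``+r_i`` for predicted
    class 1 and ``-r_i`` for predicted class 2.  Because it only uses ranks,
    any strictly increasing transform of the AD values gives the same score
    ordering.
    """
    if len(ad.values) != pred.n:
        raise ValueError("AD vector length does not match the prediction set")
    n = pred.n
    r = 1.0 - rankdata(ad.values, method="average") / (n + 1.0)
    return np.where(pred.predicted_class == 1, r, -r)


def roc_auc(scores: np.ndarray, positive: np.ndarray) -> Tuple[CurveData, float]:
    """ROC by descending score with trapezoidal AUC (mid-rank tie handling)."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if positive.all() or not positive.any():
        raise ValueError("ROC undefined: only one class present")
    fpr, tpr, _ = roc_curve(positive.astype(int), scores)
    auc = _mann_whitney_auc(scores, positive)
    curve = CurveData(kind="roc", xs=fpr, ys=tpr, n=len(scores), auc=auc)
    return curve, auc


def _mann_whitney_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic (ties count 1/2).

    Identical to the trapezoidal area under the tie-convention ROC curve.
    """
    n1 = int(positive.sum())
    n2 = len(scores) - n1
    ranks = rankdata(scores, method="average")
    u = ranks[positive].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def auc_random(sens: float, spec: float) -> float:
    """AUC of a random ranking of the prediction errors: 0.5*(Sens+Spec)."""
    _check_rates(sens, spec)
    return 0.5 * (sens + spec)


def auc_max(sens: float, spec: float) -> float:
    """Best possible signed-score AUC: 1 - (1-Sens)*(1-Spec)."""
    _check_rates(sens, spec)
    return 1.0 - (1.0 - sens) * (1.0 - spec)


def _check_rates(sens: float, spec: float) -> None:
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")


def cumulative_accuracy_curve(
    pred: PredictionSet, ad: ADScoreVector, quantiles: Optional[np.ndarray] = None
) -> CurveData:
    """Accuracy of the predictions within the nu-th AD-value quantile vs nu.

    CA(nu) is the mean correctness of objects whose AD value is at most the
    empirical nu-quantile; CA(1) is the overall accuracy.
    """
    if pred.correct is None:
        raise ValueError("correctness required for a cumulative accuracy curve")
    if quantiles is None:
        quantiles = np.linspace(0.1, 1.0, 10)
    quantiles = np.asarray(quantiles, dtype=float)
    xs, ys, thr = [], [], []
    for q in quantiles:
        cut = np.quantile(ad.values, q)
        mask = ad.values <= cut
        if not mask.any():  # empty bin: skip the point
            continue
        xs.append(q)
        ys.append(float(pred.correct[mask].mean()))
        thr.append(float(cut))
    return CurveData(
        kind="cumulative_accuracy",
        xs=np.array(xs), ys=np.array(ys), n=pred.n, thresholds=np.array(thr),
    )


def predictiveness_curve(
    pred: PredictionSet, ad: ADScoreVector, bins: int = 10
) -> CurveData:
    """Local error rate per AD-value quantile bin.

    Objects are sorted by AD value and split into ``bins`` equal-count bins;
    the y-values are per-bin error rates at bin-center quantiles, and
    ``thresholds`` holds each bin's upper AD value.
    """
    if pred.correct is None:
        raise ValueError("correctness required for a predictiveness curve")
    if bins < 1 or bins > pred.n:
        raise ValueError(f"bins={bins} invalid for n={pred.n}")
    order = np.argsort(ad.values, kind="stable")
    err = (~pred.correct[order]).astype(float)
    edges = np.linspace(0, pred.n, bins + 1).astype(int)
    xs, ys, thr = [], [], []
    for b in range(bins):
        lo, hi = edges[b], edges[b + 1]
        xs.append((lo + hi) / (2.0 * pred.n))
        ys.append(float(err[lo:hi].mean()))
        thr.append(float(ad.values[order[hi - 1]]))
    return CurveData(
        kind="predictiveness",
        xs=np.array(xs), ys=np.array(ys), n=pred.n, thresholds=np.array(thr),
    )


def permutation_test_auc(
    pred: PredictionSet,
    ad: ADScoreVector,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> Tuple[float, Dict[str, float]]:
    """Permutation test of the signed-score AUC against a random AD ranking.

    The AD values are permuted across objects B times (predictions and
    correctness held fixed) and the signed-score AUC recomputed each time;
    ``p = (1 + #{AUC_perm >= AUC_obs}) / (B + 1)``.  The summary reports the
    null median and 95th percentile; ``significant`` is p <= alpha, the
    exact-level form of requiring AUC_obs to beat the null 95th percentile.
    """
    if B < 99:
        raise ValueError("B must be at least 99")
    rng = np.random.default_rng(seed)
    n = pred.n
    positive = pred.true_class == 1
    r = 1.0 - rankdata(ad.values, method="average") / (n + 1.0)
    sign = np.where(pred.predicted_class == 1, 1.0, -1.0)
    obs = _mann_whitney_auc(sign * r, positive)
    # permuting AD values permutes their rank-normalized reliabilities
    perm = np.stack([rng.permutation(r) for _ in range(B)])
    scores = sign[None, :] * perm
    ranks = rankdata(scores, method="average", axis=1)
    n1 = int(positive.sum())
    n2 = n - n1
    null_aucs = (ranks[:, positive].sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n2)
    p = (1.0 + np.sum(null_aucs >= obs)) / (B + 1.0)
    summary = {
        "auc_obs": obs,
        "null_median": float(np.median(null_aucs)),
        "null_q95": float(np.quantile(null_aucs, 0.95)),
        "significant": p <= alpha,
    }
    return float(p), summary


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up at the printed precision.

    Works on the shortest decimal representation of ``x`` so that values such
    as 0.7965 round to 0.797 at three digits rather than falling to the
    binary-float side of the tie.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def round_auc(auc: float) -> float:
    """Round to two decimals, half away from zero (printed-table convention)."""
    return round_half_up(auc, 2)


def rank_measures(table: pd.DataFrame, rounded: bool = True) -> pd.DataFrame:
    """Rank AD measures within a classifier block across datasets.

    ``table`` has measures as rows and datasets as columns (AUC values).
    Per dataset the measures are ranked by descending (by default rounded)
    AUC, ties receiving the mean rank; the returned frame adds the per-
    dataset ranks' average as ``mean_rank`` and is sorted by it.
    """
    if table.isna().any().any():
        raise ValueError("incomplete table: every measure needs every dataset")
    vals = table.to_numpy(dtype=float)
    if rounded:
        vals = np.vectorize(round_auc)(vals)
    ranks = np.column_stack(
        [rankdata(-vals[:, j], method="average") for j in range(vals.shape[1])]
    )
    out = table.copy()
    out["mean_rank"] = ranks.mean(axis=1)
    return out.sort_values("mean_rank", kind="stable")
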