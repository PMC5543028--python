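"""Reject-option thresholding: trading coverage for a lower error rate.

Objects with AD values at most the threshold are "inside" the applicability
domain; predictions outside are rejected.  Three strategies resolve a
threshold: a quantile of the training set's AD values, a cap on the local
error rate read off a predictiveness curve, or a target overall accuracy
read off a cumulative-accuracy curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from adbench.confidence import PredictionSet
from adbench.evaluation import ADScoreVector, CurveData


@dataclass
class RejectThreshold:
    strategy: str  # "training_quantile" | "local_error_limit" | "accuracy_target"
    parameter: float
    threshold_value: float  # AD-value cutoff; <= is inside the AD


def threshold_by_training_quantile(
    train_ad: ADScoreVector, x_percent: float
) -> RejectThreshold:
    """Threshold at the (100 - x)% quantile of the training AD values.

    Excludes the x% most extreme training objects (and any future object
    more extreme than that).  Uses the linear-interpolation quantile.
    """
    if not 0.0 <= x_percent < 100.0:
        raise ValueError("x_percent must lie in [0, 100)")
    if len(train_ad.values) == 0:
        raise ValueError("empty training AD vector")
    thr = float(np.quantile(train_ad.values, 1.0 - x_percent / 100.0))
    return RejectThreshold("training_quantile", x_percent, thr)


def threshold_by_local_error(curve: CurveData, limit: float) -> RejectThreshold:
    """Largest AD quantile whose local error rate (and all earlier bins') <= limit."""
    if curve.kind != "predictiveness":
        raise ValueError("a predictiveness curve is required")
    if not 0.0 < limit <= 1.0:
        raise ValueError("limit must lie in (0, 1]")
    ok = np.flatnonzero(np.maximum.accumulate(curve.ys) <= limit)
    if ok.size == 0:
        warnings.warn("no bin satisfies the local error limit: rejecting everything",
                      stacklevel=2)
        return RejectThreshold("local_error_limit", limit, -np.inf)
    last = ok[-1]
    return RejectThreshold("local_error_limit", limit, float(curve.thresholds[last]))


def threshold_by_accuracy_target(ca: CurveData, target: float) -> RejectThreshold:
    """Largest AD quantile nu with cumulative accuracy CA(nu) >= target."""
    if ca.kind != "cumulative_accuracy":
        raise ValueError("a cumulative-accuracy curve is required")
    if not 0.0 < target <= 1.0:
        raise ValueError("target must lie in (0, 1]")
    ok = np.flatnonzero(ca.ys >= target)
    if ok.size == 0:
        warnings.warn("accuracy target unreachable at any quantile: rejecting everything",
                      stacklevel=2)
        return RejectThreshold("accuracy_target", target, -np.inf)
    last = ok[-1]
    return RejectThreshold("accuracy_target", target, float(ca.thresholds[last]))


def apply_reject(
    ad: ADScoreVector, thr: RejectThreshold, pred: PredictionSet
) -> Tuple[float, float, float]:
    """(coverage, error_rate_inside, error_rate_outside) under a threshold.

    Error rates of empty partitions are NaN.  Bookkeeping is exact:
    inside errors + outside errors = total errors.
    """
    if len(ad.values) != pred.n:
        raise ValueError("AD vector length does not match the prediction set")
    if pred.correct is None:
        raise ValueError("correctness required to evaluate the reject option")
    inside = ad.values <= thr.threshold_value
    coverage = float(inside.mean())
    err = ~pred.correct
    err_in = float(err[inside].mean()) if inside.any() else float("nan")
    err_out = float(err[~inside].mean()) if (~inside).any() else float("nan")
    return coverage, err_in, err_out
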