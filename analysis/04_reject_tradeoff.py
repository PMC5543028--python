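"""Reject-option trade-off: coverage vs error rate under three strategies.

For the intermediate-difficulty dataset and a random forest's class-
probability confidence measure, resolves reject thresholds by (a) training-
set AD quantiles (x = 0..50%), (b) local-error-rate caps on the
predictiveness curve, and (c) cumulative-accuracy targets, then reports the
coverage and the error rate among the retained ("inside the AD")
predictions.  With an informative confidence measure the inside error rate
falls well below the overall error rate as coverage shrinks; in particular
rejecting at the 80% training quantile avoids most of the high-local-error
tail.

Writes results/reject_tradeoff.csv.
"""

from pathlib import Path

import pandas as pd

from adbench.confidence import ClassifierSpec, collect_confidence
from adbench.datasets import read_dataset_csv
from adbench.evaluation import (
    ADScoreVector,
    cumulative_accuracy_curve,
    predictiveness_curve,
)
from adbench.pipeline import _prepare_matrix
from adbench.reject import (
    apply_reject,
    threshold_by_accuracy_target,
    threshold_by_local_error,
    threshold_by_training_quantile,
)
from adbench.validation import kfold_split, run_cv

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 2024


def main() -> None:
    ds = _prepare_matrix(read_dataset_csv(ROOT / "data" / "gauss_intermediate.csv"))
    spec = ClassifierSpec(family="RF", seed=SEED)
    folds = kfold_split(ds.n, 5, seed=SEED, labels=ds.y)
    pred = run_cv(ds, spec, folds)
    ad = ADScoreVector(
        "p_hat_error_RFC", "confidence", collect_confidence(pred, spec)["p_hat_error"]
    )
    overall_err = 1.0 - pred.correct.mean()
    print(f"overall CV error rate: {overall_err:.3f}\n")

    rows = []
    for x in (0.0, 10.0, 20.0, 30.0, 40.0, 50.0):
        thr = threshold_by_training_quantile(ad, x)
        cov, err_in, err_out = apply_reject(ad, thr, pred)
        rows.append(("training_quantile", x, thr.threshold_value, cov, err_in, err_out))
    pc = predictiveness_curve(pred, ad)
    for limit in (0.3, 0.2, 0.1):
        thr = threshold_by_local_error(pc, limit)
        cov, err_in, err_out = apply_reject(ad, thr, pred)
        rows.append(("local_error_limit", limit, thr.threshold_value, cov, err_in, err_out))
    ca = cumulative_accuracy_curve(pred, ad)
    for target in (0.85, 0.9, 0.95):
        thr = threshold_by_accuracy_target(ca, target)
        cov, err_in, err_out = apply_reject(ad, thr, pred)
        rows.append(("accuracy_target", target, thr.threshold_value, cov, err_in, err_out))

    df = pd.DataFrame(rows, columns=[
        "strategy", "parameter", "threshold", "coverage",
        "error_inside", "error_outside",
    ])
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    df.to_csv(ROOT / "reject_tradeoff.csv", index=False)
    print(f"\nwrote {ROOT / 'reject_tradeoff.csv'}")


if __name__ == "__main__":
    main()
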