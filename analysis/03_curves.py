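"""Performance curves for one dataset: ROC, cumulative accuracy, predictiveness.

For the intermediate-difficulty Gaussian dataset and a random forest, plots
the three benchmark curves for the built-in class-probability confidence
measure against two novelty measures (cos_alpha and gamma_Euc).  On an
intermediate problem the confidence curve should ascend steeply while the
novelty curves run close to the random-ranking diagonal; the cumulative
accuracy of the confidence measure starts near 1 and decays, and its
predictiveness curve shows the sharp error-rate increase in the last
quantiles that makes a reject option worthwhile.

Writes per-curve CSV point lists and results/figures/curves_rf.png.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from adbench.confidence import ClassifierSpec, collect_confidence
from adbench.datasets import read_dataset_csv
from adbench.evaluation import (
    ADScoreVector,
    ad_ranking_score,
    auc_max,
    auc_random,
    cumulative_accuracy_curve,
    predictiveness_curve,
    roc_auc,
)
from adbench.pipeline import _prepare_matrix, pooled_novelty_scores
from adbench.validation import confusion_metrics, kfold_split, run_cv

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 2024


def main() -> None:
    ds = _prepare_matrix(read_dataset_csv(ROOT / "data" / "gauss_intermediate.csv"))
    spec = ClassifierSpec(family="RF", seed=SEED)
    folds = kfold_split(ds.n, 5, seed=SEED, labels=ds.y)
    pred = run_cv(ds, spec, folds)
    cm = confusion_metrics(pred)
    print(f"RF on {ds.name}: acc={cm.acc:.3f} sens={cm.sens:.3f} spec={cm.spec:.3f}")
    print(f"closed-form bounds: AUC_random={auc_random(cm.sens, cm.spec):.3f} "
          f"AUC_max={auc_max(cm.sens, cm.spec):.3f}")

    measures = {"p_hat_error_RFC": collect_confidence(pred, spec)["p_hat_error"]}
    novelty = pooled_novelty_scores(ds, folds)
    measures["cos_alpha"] = novelty["cos_alpha"]
    measures["gamma_Euc"] = novelty["gamma_Euc"]

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    out_rows = []
    for name, values in measures.items():
        cat = "confidence" if name.startswith("p_hat") else "novelty"
        ad = ADScoreVector(name, cat, values)
        roc, auc = roc_auc(ad_ranking_score(pred, ad), pred.true_class == 1)
        ca = cumulative_accuracy_curve(pred, ad)
        pc = predictiveness_curve(pred, ad)
        print(f"  {name:16s} signed-score AUC ROC = {auc:.3f}")
        axes[0].plot(roc.xs, roc.ys, label=f"{name} ({auc:.3f})")
        axes[1].plot(ca.xs, ca.ys, marker="o", label=name)
        axes[2].plot(pc.xs, pc.ys, marker="o", label=name)
        for curve, kind in ((roc, "roc"), (ca, "ca"), (pc, "predictiveness")):
            for x, y in zip(curve.xs, curve.ys):
                out_rows.append({"measure": name, "curve": kind, "x": x, "y": y})
    axes[0].plot([0, 1], [0, 1], "k--", lw=0.5)
    axes[0].set(xlabel="1 - specificity", ylabel="sensitivity", title="signed-score ROC")
    axes[1].set(xlabel="AD quantile", ylabel="cumulative accuracy", title="CA curve")
    axes[2].set(xlabel="AD quantile", ylabel="local error rate", title="predictiveness")
    for ax in axes:
        ax.legend(fontsize=7)
    fig.tight_layout()
    (ROOT / "figures").mkdir(parents=True, exist_ok=True)
    fig.savefig(ROOT / "figures" / "curves_rf.png", dpi=150)
    pd.DataFrame(out_rows).to_csv(ROOT / "curves_rf.csv", index=False)
    print(f"wrote {ROOT / 'figures' / 'curves_rf.png'} and curves_rf.csv")


if __name__ == "__main__":
    main()
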