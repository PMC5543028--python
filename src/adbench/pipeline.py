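"""End-to-end benchmark: datasets x classifier families x AD measures.

For each dataset the descriptor matrix is autoscaled on the entire matrix
(binary fingerprints are left raw), stratified fivefold CV produces pooled
out-of-fold predictions per classifier family (random-undersampling CV when
the minority class is below 40%), novelty scores are computed out-of-fold
with the same partitions, and every AD measure is summarized by its
signed-score ROC AUC with permutation significance.  Measures are then
ranked within each classifier block across datasets by rounded AUC, the
layout of a classical benchmark table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from adbench.confidence import (
    REGRESSION_FAMILIES,
    ClassifierSpec,
    PredictionSet,
    collect_confidence,
)
from adbench.datasets import LabeledDataset
from adbench.evaluation import (
    ADScoreVector,
    ad_ranking_score,
    permutation_test_auc,
    rank_measures,
    roc_auc,
    round_auc,
)
from adbench.novelty import NOVELTY_MEASURES, score_novelty
from adbench.preprocessing import autoscale
from adbench.validation import (
    RUS_MINORITY_THRESHOLD,
    kfold_split,
    run_cv,
    rus_cv,
)

DEFAULT_FAMILIES = ("RF", "NN", "SVM", "MB", "kNN", "LDA")


@dataclass
class BenchmarkTable:
    """Per (family, measure, dataset) AUCs with significance and mean ranks."""

    records: pd.DataFrame  # family, measure, category, dataset, auc, auc_rounded, p_value, significant

    def block(self, family: str) -> pd.DataFrame:
        """Measure x dataset table of AUCs for one classifier family."""
        sub = self.records[self.records["family"] == family]
        return sub.pivot(index="measure", columns="dataset", values="auc")

    def summary(self) -> pd.DataFrame:
        """Mean rank and significance count per (family, measure)."""
        rows = []
        for family in self.records["family"].unique():
            sub = self.records[self.records["family"] == family]
            ranked = rank_measures(self.block(family))
            nsig = sub.groupby("measure")["significant"].sum()
            cat = sub.groupby("measure")["category"].first()
            for measure, row in ranked.iterrows():
                rows.append({
                    "family": family,
                    "measure": measure,
                    "category": cat[measure],
                    "mean_rank": row["mean_rank"],
                    "n_significant": int(nsig[measure]),
                })
        return pd.DataFrame(rows)

    def report(self) -> str:
        """Plain-text report: per-family blocks of rounded AUCs, sorted by rank."""
        lines: List[str] = []
        datasets = list(self.records["dataset"].unique())
        for family in self.records["family"].unique():
            ranked = rank_measures(self.block(family))
            lines.append(f"== {family} ==")
            header = "measure".ljust(22) + "".join(d[:10].rjust(11) for d in datasets)
            lines.append(header + "  mean_rank  #signif")
            nsig = (
                self.records[self.records["family"] == family]
                .groupby("measure")["significant"].sum()
            )
            for measure, row in ranked.iterrows():
                cells = "".join(f"{round_auc(row[d]):11.2f}" for d in datasets)
                lines.append(
                    measure.ljust(22) + cells
                    + f"{row['mean_rank']:11.2f}" + f"{int(nsig[measure]):9d}"
                )
            lines.append("")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def _prepare_matrix(ds: LabeledDataset) -> LabeledDataset:
    if ds.feature_kind == "binary":
        return ds
    scaled = autoscale(ds.X)
    return replace_X(ds, scaled.X_scaled)


def replace_X(ds: LabeledDataset, X: np.ndarray) -> LabeledDataset:
    return LabeledDataset(
        X=X, y=ds.y, feature_kind=ds.feature_kind, novel_flag=ds.novel_flag, name=ds.name
    )


def pooled_novelty_scores(
    ds: LabeledDataset, folds, k: int = 5
) -> Dict[str, np.ndarray]:
    """Out-of-fold novelty AD values: each object scored against the training
    objects of the folds it does not belong to."""
    out = {name: np.empty(ds.n) for name in NOVELTY_MEASURES}
    for fold in range(1, folds.K + 1):
        tr = folds.train_indices(fold)
        te = folds.test_indices(fold)
        scores = score_novelty(ds.subset(tr), ds.X[te], k=k)
        for name in NOVELTY_MEASURES:
            out[name][te] = scores[name]
    return out


def _specs_for(
    family: str, include_regression: bool, seed: int, knn_k: int
) -> List[ClassifierSpec]:
    specs = [ClassifierSpec(family=family, mode="classification", seed=seed, k=knn_k)]
    if include_regression and family in REGRESSION_FAMILIES:
        specs.append(ClassifierSpec(family=family, mode="regression", seed=seed, k=knn_k))
    return specs


def benchmark(
    datasets: Sequence[LabeledDataset],
    families: Sequence[str] = DEFAULT_FAMILIES,
    include_regression: bool = True,
    k_folds: int = 5,
    knn_k: int = 5,
    B: int = 1000,
    seed: int = 0,
    rus_repeats: int = 10,
    use_rus: Optional[bool] = None,
    measures: Optional[Sequence[str]] = None,
) -> BenchmarkTable:
    """Run the full AD-measure benchmark and assemble the results table.

    ``use_rus=None`` applies the automatic rule (RUS CV iff the minority
    class is below 40%); True/False forces it on or off.  ``measures``
    restricts the table to the named AD measures (names as they appear in
    the records, e.g. ``p_hat_error_RFC`` or ``cos_alpha``).  All randomness
    (folds, undersampling, classifier seeds, permutations) flows from
    ``seed``.
    """
    root = np.random.default_rng(seed)
    rows = []
    for ds in datasets:
        ds_seed = int(root.integers(2**31 - 1))
        prepared = _prepare_matrix(ds)
        folds = kfold_split(prepared.n, k_folds, seed=ds_seed, labels=prepared.y)
        novelty = pooled_novelty_scores(prepared, folds, k=knn_k)
        minority = min(float(np.mean(prepared.y == 1)), float(np.mean(prepared.y == 2)))
        rus = minority < RUS_MINORITY_THRESHOLD if use_rus is None else use_rus
        for family in families:
            fam_seed = int(root.integers(2**31 - 1))
            cls_pred: Optional[PredictionSet] = None
            for spec in _specs_for(family, include_regression, fam_seed, knn_k):
                if rus:
                    pred = rus_cv(prepared, spec, K=k_folds,
                                  repeats=rus_repeats, seed=ds_seed)
                else:
                    pred = run_cv(prepared, spec, folds)
                if spec.mode == "classification":
                    cls_pred = pred
                conf = collect_confidence(pred, spec)
                for mname, values in conf.items():
                    rows.append(_evaluate_measure(
                        pred, f"{mname}_{spec.label}", "confidence", values,
                        ds.name, family, B, int(root.integers(2**31 - 1)),
                    ))
            # novelty measures are benchmarked against the family's
            # classification-mode predictions
            for mname in NOVELTY_MEASURES:
                rows.append(_evaluate_measure(
                    cls_pred, mname, "novelty", novelty[mname],
                    ds.name, family, B, int(root.integers(2**31 - 1)),
                ))
    records = pd.DataFrame(rows)
    if measures is not None:
        records = records[records["measure"].isin(measures)].reset_index(drop=True)
    return BenchmarkTable(records=records)


def _evaluate_measure(
    pred: PredictionSet,
    measure: str,
    category: str,
    values: np.ndarray,
    dataset: str,
    family: str,
    B: int,
    seed: int,
) -> dict:
    ad = ADScoreVector(name=measure, category=category, values=values)
    scores = ad_ranking_score(pred, ad)
    _, auc = roc_auc(scores, pred.true_class == 1)
    p, summary = permutation_test_auc(pred, ad, B=B, seed=seed)
    return {
        "family": family,
        "measure": measure,
        "category": category,
        "dataset": dataset,
        "auc": auc,
        "auc_rounded": round_auc(auc),
        "p_value": p,
        "significant": bool(summary["significant"]),
    }
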