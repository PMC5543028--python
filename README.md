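# adbench

Benchmarking applicability-domain measures for binary classifiers in
cheminformatics.

A QSAR classifier's prediction for a new compound is only as good as the
compound's position relative to the model: far from the training data, or
close to the decision boundary, the error probability rises.  *Applicability
domain* (AD) measures score each object so that larger values mean a less
reliable prediction.  This package implements the two families of AD
measures used in practice and the benchmarking machinery to rank them:

* **novelty measures** (descriptors only): the DA-index κ, γ, δ with
  Euclidean or Tanimoto distance, and the mean-cosine measure
  1 − cos α — all with k = 5 nearest neighbors;
* **confidence measures** (classifier-derived): class-probability error
  1 − p̂, CLASS-LAG = min(|ŷ|, |1 − ŷ|), ensemble standard deviation STD,
  PROB-STD = Φ(−|ŷ − 0.5|/σ̂), vote-fraction error 1 − ν̂, and boosting-
  margin error 1 − |f̄|;

for six classifier families (random forest, neural-network ensemble, SVM,
bagged AdaBoost stumps, k-NN, LDA; RF/NN/SVM also in regression mode
against 0/1 targets).

Each measure is judged by how well its *signed reliability score*
(+r for predicted class 1, −r for predicted class 2, with r the
rank-normalized reliability) separates the true classes in a ROC analysis
under stratified fivefold cross-validation, with permutation significance
and mean-rank aggregation across datasets.  Two closed forms anchor the
construction: a random ranking of the errors gives
AUC_random = 0.5·(Sens + Spec), an ideal measure gives
AUC_max = 1 − (1 − Sens)·(1 − Spec).  Reject-option thresholding (training
quantile, local-error cap, accuracy target) turns a measure into a
coverage/error-rate trade-off.  A seeded synthetic-data module generates
datasets with the statistical structure of public QSAR benchmarks, so the
entire pipeline runs end-to-end without downloads.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from adbench import (
    GeneratorSpec, generate_gaussian_dataset, ClassifierSpec,
    kfold_split, run_cv, collect_confidence, confusion_metrics,
    ADScoreVector, ad_ranking_score, roc_auc, auc_random, auc_max,
    permutation_test_auc,
)

ds = generate_gaussian_dataset(
    GeneratorSpec(n=600, p=166, separation=0.36, informative_fraction=0.1,
                  seed=2024))
spec = ClassifierSpec(family="RF", seed=2024)
folds = kfold_split(ds.n, 5, seed=2024, labels=ds.y)
pred = run_cv(ds, spec, folds)

cm = confusion_metrics(pred)
print(f"sens={cm.sens:.3f} spec={cm.spec:.3f}")
print(f"AUC_random={auc_random(cm.sens, cm.spec):.3f} "
      f"AUC_max={auc_max(cm.sens, cm.spec):.3f}")

ad = ADScoreVector("p_hat_error_RFC", "confidence",
                   collect_confidence(pred, spec)["p_hat_error"])
_, auc = roc_auc(ad_ranking_score(pred, ad), pred.true_class == 1)
p, _ = permutation_test_auc(pred, ad, B=999, seed=2024)
print(f"signed-score AUC ROC = {auc:.3f} (permutation p = {p:.3f})")
```

prints

```
sens=0.703 spec=0.683
AUC_random=0.693 AUC_max=0.906
signed-score AUC ROC = 0.760 (permutation p = 0.001)
```

The random forest's class-probability measure ranks its own errors far
better than chance (0.760 vs the 0.693 a random ordering would give), but
stays well below the ideal 0.906 — class-probability estimates are never
exact.

## The analysis

Numbered drivers under `analysis/` rerun the full study on synthetic data
and write their tables to `results/`:

1. `01_generate_datasets.py` — five datasets (easy/intermediate/hard
   Gaussian, fingerprint-like binary, intermediate with 10% injected novel
   objects) as CSV;
2. `02_benchmark.py` — the full measure × family × dataset benchmark with
   permutation significance and mean ranks (`benchmark_table.csv`,
   `benchmark_report.txt`, `benchmark_summary.csv`), and the check that in
   every classifier block the confidence measures out-rank the novelty
   measures;
3. `03_curves.py` — ROC / cumulative-accuracy / predictiveness curves for
   a confidence measure against two novelty measures on the intermediate
   dataset;
4. `04_reject_tradeoff.py` — coverage vs error rate under the three
   reject-threshold strategies.

The same machinery is scriptable from a shell via the `adbench` CLI
(`generate`, `benchmark`, `curves`, `reject` subcommands; YAML
configuration, one top-level seed).

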