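"""Generate the synthetic benchmark suite.

Writes five labeled descriptor tables to results/data/: three Gaussian
datasets spanning the easy / intermediate / hard difficulty regimes, one
fingerprint-like binary dataset, and one intermediate dataset with 10%
injected novel objects (displaced far from the training density, labels
kept).  Sizes and class ratios follow the ranges of published QSAR
benchmark collections (a few hundred to a few thousand objects, ~166
descriptors, class ratios between 15/85 and 62/38).
"""

from pathlib import Path

import numpy as np

from adbench.datasets import (
    GeneratorSpec,
    generate_fingerprint_dataset,
    generate_gaussian_dataset,
    informative_indices,
    inject_novel_objects,
    separation_for_bayes_auc,
    write_dataset_csv,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 2024

# per-descriptor separations calibrated through the closed-form Bayes AUC
M_INFORMATIVE = len(informative_indices(166, 0.1))
REGIMES = {
    "easy": separation_for_bayes_auc(0.99, M_INFORMATIVE),
    "intermediate": separation_for_bayes_auc(0.85, M_INFORMATIVE),
    "hard": separation_for_bayes_auc(0.62, M_INFORMATIVE),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    datasets = []
    for i, (regime, sep) in enumerate(REGIMES.items()):
        ds = generate_gaussian_dataset(
            GeneratorSpec(n=600, p=166, class_ratio=0.42, separation=sep,
                          informative_fraction=0.1, seed=SEED + i),
            name=f"gauss_{regime}",
        )
        datasets.append(ds)

    rng = np.random.default_rng(SEED + 10)
    q_base = rng.uniform(0.1, 0.5, 166)
    q1, q2 = q_base.copy(), q_base.copy()
    informative = rng.choice(166, size=25, replace=False)
    q1[informative] = np.clip(q_base[informative] + 0.25, 0, 1)
    q2[informative] = np.clip(q_base[informative] - 0.15, 0, 1)
    datasets.append(generate_fingerprint_dataset(
        GeneratorSpec(n=800, p=166, class_ratio=0.35, seed=SEED + 11),
        q1, q2, name="fingerprint",
    ))

    novel = inject_novel_objects(
        generate_gaussian_dataset(
            GeneratorSpec(n=600, p=166, class_ratio=0.5,
                          separation=REGIMES["intermediate"],
                          informative_fraction=0.1, seed=SEED + 20),
            name="gauss_novel",
        ),
        fraction=0.10, shift=5.0, seed=SEED + 21,
    )
    datasets.append(novel)

    for ds in datasets:
        path = OUT / f"{ds.name}.csv"
        write_dataset_csv(ds, path)
        n1 = int(np.sum(ds.y == 1))
        print(f"{ds.name:20s} n={ds.n:5d} p={ds.p} class ratio {n1}/{ds.n - n1} "
              f"kind={ds.feature_kind}"
              + (f" novel={int(ds.novel_flag.sum())}" if ds.novel_flag is not None else ""))
    print(f"\nwrote {len(datasets)} datasets to {OUT}")


if __name__ == "__main__":
    main()
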