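"""Synthetic labeled datasets with the statistical structure of QSAR benchmarks.

Two-class descriptor tables are generated either as multivariate Gaussians
(continuous descriptors, class overlap controlled by a separation parameter)
or as fingerprint-like independent Bernoulli bits with class-conditional
on-probabilities.  A fraction of objects can be displaced far from the
training density and flagged as "novel", emulating remote query compounds.
All generators are pure functions of their arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm


class EmptyClassError(ValueError):
    """Requested class sizes leave one class without objects."""


@dataclass
class LabeledDataset:
    """A descriptor matrix with two-class labels and optional novelty flags.

    Labels are coded 1 and 2 (class 1 is the "positive" class throughout the
    package).  ``feature_kind`` is ``"continuous"`` or ``"binary"``; binary
    matrices contain only 0/1 entries.
    """

    X: np.ndarray
    y: np.ndarray
    feature_kind: str = "continuous"
    novel_flag: Optional[np.ndarray] = None
    name: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if len(self.y) != self.n:
            raise ValueError("y length does not match X")
        if self.n < 2:
            raise ValueError("a dataset needs at least 2 objects")
        if not np.isin(self.y, (1, 2)).all():
            raise ValueError("labels must be coded 1/2")
        if self.feature_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if self.feature_kind == "binary" and not np.isin(self.X, (0.0, 1.0)).all():
            raise ValueError("binary datasets must contain only 0/1 entries")
        if self.novel_flag is not None:
            self.novel_flag = np.asarray(self.novel_flag, dtype=bool)
            if len(self.novel_flag) != self.n:
                raise ValueError("novel_flag length does not match X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray, name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            X=self.X[idx],
            y=self.y[idx],
            feature_kind=self.feature_kind,
            novel_flag=None if self.novel_flag is None else self.novel_flag[idx],
            name=self.name if name is None else name,
        )


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a synthetic two-class dataset.

    ``class_ratio`` is the fraction of objects in class 1; ``separation`` is
    the per-descriptor mean difference between the classes along the
    informative descriptors (within-class variance is 1), so the total
    between-class Mahalanobis distance is ``separation * sqrt(m)`` for ``m``
    informative descriptors.
    """

    n: int
    p: int
    class_ratio: float = 0.5
    separation: float = 1.0
    informative_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if not 0.0 < self.class_ratio < 1.0:
            raise ValueError("class_ratio must be in (0, 1)")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")
        if not 0.0 < self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must be in (0, 1]")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _class_sizes(n: int, class_ratio: float) -> tuple[int, int]:
    n1 = _round_half_up(n * class_ratio)
    if n1 < 1 or n1 >= n:
        raise EmptyClassError(
            f"class sizes {n1}/{n - n1} leave a class empty (n={n}, ratio={class_ratio})"
        )
    return n1, n - n1  # remainder goes to class 2


def informative_indices(p: int, informative_fraction: float) -> np.ndarray:
    """Indices of the descriptors carrying class signal, spread evenly over 1..p."""
    m = max(1, _round_half_up(p * informative_fraction))
    return np.unique(np.round(np.linspace(0, p - 1, m)).astype(int))


def separation_for_bayes_auc(target_auc: float, n_informative: int) -> float:
    """Per-descriptor separation giving a target Bayes ROC AUC.

    For two unit-variance Gaussian classes whose means differ by ``d`` along
    each of ``m`` informative descriptors, the optimal score is Gaussian in
    each class with between-class distance ``Delta = d*sqrt(m)`` and the
    Bayes ROC AUC is ``Phi(Delta/sqrt(2))``.  Inverting gives the ``d``
    needed to place a problem in a desired difficulty regime (e.g. the
    intermediate band 0.7-0.9).
    """
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target_auc must be in (0.5, 1)")
    delta = np.sqrt(2.0) * norm.ppf(target_auc)
    return float(delta / np.sqrt(n_informative))


def generate_gaussian_dataset(spec: GeneratorSpec, name: str = "") -> LabeledDataset:
    """Two multivariate-normal classes with unit within-class variance.

    Class means sit at +separation/2 (class 1) and -separation/2 (class 2)
    on each informative descriptor and at 0 elsewhere, keeping the pooled
    mean at the origin.  Class sizes are round(n*class_ratio) for class 1,
    remainder to class 2.  Deterministic in ``spec``.
    """
    n1, n2 = _class_sizes(spec.n, spec.class_ratio)
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n, spec.p))
    y = np.concatenate([np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)])
    info = informative_indices(spec.p, spec.informative_fraction)
    X[:n1, info] += spec.separation / 2.0
    X[n1:, info] -= spec.separation / 2.0
    return LabeledDataset(X=X, y=y, feature_kind="continuous", name=name)


def generate_fingerprint_dataset(
    spec: GeneratorSpec,
    p_on_class1: Sequence[float],
    p_on_class2: Sequence[float],
    name: str = "",
) -> LabeledDataset:
    """Binary fingerprint-like descriptors from class-conditional bit probabilities.

    Each bit is drawn independently per object with the on-probability of the
    object's class, emulating substructure-key fingerprints.  ``spec.separation``
    and ``spec.informative_fraction`` are ignored; the signal is entirely in
    the two probability vectors (each of length ``spec.p``).
    """
    q1 = np.asarray(p_on_class1, dtype=float)
    q2 = np.asarray(p_on_class2, dtype=float)
    if q1.shape != (spec.p,) or q2.shape != (spec.p,):
        raise ValueError("bit-probability lists must have length p")
    for q in (q1, q2):
        if ((q < 0) | (q > 1)).any():
            raise ValueError("bit probabilities must lie in [0, 1]")
    n1, n2 = _class_sizes(spec.n, spec.class_ratio)
    rng = np.random.default_rng(spec.seed)
    X1 = (rng.random((n1, spec.p)) < q1).astype(float)
    X2 = (rng.random((n2, spec.p)) < q2).astype(float)
    X = np.vstack([X1, X2])
    y = np.concatenate([np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)])
    return LabeledDataset(X=X, y=y, feature_kind="binary", name=name)


def inject_novel_objects(
    ds: LabeledDataset, fraction: float, shift: float, seed: int
) -> LabeledDataset:
    """Displace a random fraction of objects away from the training density.

    Each selected object is moved by a vector of length ``shift*sqrt(p)`` in
    its own uniformly random direction; displaced objects get
    ``novel_flag=True``, all others ``False``.  Labels are kept, so a novel
    object is "remote but possibly still correctly classified".
    """
    if ds.feature_kind != "continuous":
        raise ValueError("novel-object injection requires continuous descriptors")
    if shift < 0:
        raise ValueError("shift must be nonnegative")
    n_sel = _round_half_up(fraction * ds.n)
    if not 0.0 < fraction < 1.0 or n_sel < 1:
        raise ValueError(f"fraction={fraction} selects no objects (n={ds.n})")
    rng = np.random.default_rng(seed)
    sel = rng.choice(ds.n, size=n_sel, replace=False)
    direc = rng.standard_normal((n_sel, ds.p))
    direc /= np.linalg.norm(direc, axis=1, keepdims=True)
    X = ds.X.copy()
    X[sel] += shift * np.sqrt(ds.p) * direc
    flags = np.zeros(ds.n, dtype=bool)
    flags[sel] = True
    return LabeledDataset(
        X=X, y=ds.y.copy(), feature_kind="continuous", novel_flag=flags, name=ds.name
    )


# ---------------------------------------------------------------------------
# CSV round-trip: descriptor columns, final columns `label` and optional `novel`

def write_dataset_csv(ds: LabeledDataset, path: str | Path) -> None:
    cols = {f"d{j + 1}": ds.X[:, j] for j in range(ds.p)}
    cols["label"] = ds.y
    if ds.novel_flag is not None:
        cols["novel"] = ds.novel_flag.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_dataset_csv(path: str | Path, name: str | None = None) -> LabeledDataset:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing required `label` column")
    novel = None
    if "novel" in df.columns:
        novel = df.pop("novel").to_numpy(dtype=bool)
    y = df.pop("label").to_numpy(dtype=int)
    X = df.to_numpy(dtype=float)
    kind = "binary" if np.isin(X, (0.0, 1.0)).all() else "continuous"
    return LabeledDataset(
        X=X, y=y, feature_kind=kind, novel_flag=novel,
        name=Path(path).stem if name is None else name,
    )
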