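"""Label-free novelty measures: the DA-index (kappa, gamma, delta) and mean cosine.

For a query object and its k nearest training neighbors (k = 5 by default,
ties at rank k broken by training-set index order):

* ``kappa`` — distance to the kth-nearest neighbor,
* ``gamma`` — mean distance to the k nearest neighbors,
* ``delta`` — length of the mean difference vector (neighbor - query);
  symmetric neighborhoods cancel, so well-embedded objects get small delta
  even when gamma is large,
* ``cosine_ad`` — one minus the mean cosine similarity to the k most
  cosine-similar neighbors.

Neighbor selection can use Euclidean or Tanimoto distance; delta is always a
Euclidean vector length in descriptor space (Tanimoto induces no vector
geometry).  None of the measures ever reads a class label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from adbench.datasets import LabeledDataset
from adbench.preprocessing import (
    EUCLIDEAN,
    METRICS,
    TANIMOTO,
    pairwise_cosine,
    pairwise_distances,
)

DEFAULT_K = 5

#: canonical names of the seven novelty AD score vectors, in report order
NOVELTY_MEASURES = (
    "kappa_Euc",
    "gamma_Euc",
    "delta_Euc",
    "kappa_Tan",
    "gamma_Tan",
    "delta_Tan",
    "cos_alpha",
)


class InsufficientNeighborsError(ValueError):
    pass


@dataclass
class NoveltyScores:
    """Per-object novelty AD values for all seven measure variants.

    ``scores`` maps measure name (see :data:`NOVELTY_MEASURES`) to a vector
    of AD values oriented so that larger = less reliable.
    """

    scores: Dict[str, np.ndarray]
    k: int

    def __getitem__(self, name: str) -> np.ndarray:
        return self.scores[name]


def _check_k(k: int, n_train: int) -> None:
    if k < 1:
        raise ValueError("k must be positive")
    if k > n_train:
        raise InsufficientNeighborsError(
            f"k={k} exceeds the {n_train} available training objects"
        )


def _knn_indices(dist_row: np.ndarray, k: int) -> np.ndarray:
    # stable sort => ties broken by training index order
    return np.argsort(dist_row, kind="stable")[:k]


def da_index(
    train_X: np.ndarray, query: np.ndarray, k: int = DEFAULT_K, metric: str = EUCLIDEAN
) -> Tuple[float, float, float]:
    """(kappa, gamma, delta) of one query against a training matrix."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    train_X = np.asarray(train_X, dtype=float)
    query = np.asarray(query, dtype=float)
    _check_k(k, train_X.shape[0])
    d = pairwise_distances(query[None, :], train_X, metric)[0]
    nn = _knn_indices(d, k)
    kappa = float(d[nn[-1]])
    gamma = float(d[nn].mean())
    mean_vec = (train_X[nn] - query).mean(axis=0)
    delta = float(np.linalg.norm(mean_vec))
    return kappa, gamma, delta


def cosine_ad(train_X: np.ndarray, query: np.ndarray, k: int = DEFAULT_K) -> float:
    """One minus the mean cosine similarity to the k most similar neighbors."""
    train_X = np.asarray(train_X, dtype=float)
    query = np.asarray(query, dtype=float)
    _check_k(k, train_X.shape[0])
    sims = pairwise_cosine(query[None, :], train_X)[0]
    top = np.argsort(-sims, kind="stable")[:k]
    return 1.0 - float(sims[top].mean())


def _score_block(
    train_X: np.ndarray, test_X: np.ndarray, k: int, metric: str, exclude_self: bool
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = pairwise_distances(test_X, train_X, metric)
    if exclude_self:
        np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    rows = np.arange(test_X.shape[0])[:, None]
    dk = d[rows, order]
    kappa = dk[:, -1]
    gamma = dk.mean(axis=1)
    # delta in raw descriptor space with the Euclidean norm, for either metric
    mean_vec = train_X[order].mean(axis=1) - test_X
    delta = np.linalg.norm(mean_vec, axis=1)
    return kappa, gamma, delta


def score_novelty(
    train: LabeledDataset,
    test_X: np.ndarray,
    k: int = DEFAULT_K,
    exclude_self: bool = False,
) -> NoveltyScores:
    """All seven novelty AD score vectors for a test matrix.

    With ``exclude_self=True`` the i-th test object is assumed to be the
    i-th training object and is left out of its own neighbor search
    (training-set self-scoring, mirroring the CV design where test objects
    are disjoint from training).
    """
    test_X = np.asarray(test_X, dtype=float)
    n_avail = train.n - (1 if exclude_self else 0)
    _check_k(k, n_avail)
    if exclude_self and test_X.shape[0] != train.n:
        raise ValueError("exclude_self requires test_X to be the training matrix")
    scores: Dict[str, np.ndarray] = {}
    for metric, tag in ((EUCLIDEAN, "Euc"), (TANIMOTO, "Tan")):
        kappa, gamma, delta = _score_block(train.X, test_X, k, metric, exclude_self)
        scores[f"kappa_{tag}"] = kappa
        scores[f"gamma_{tag}"] = gamma
        scores[f"delta_{tag}"] = delta
    sims = pairwise_cosine(test_X, train.X)
    if exclude_self:
        np.fill_diagonal(sims, -np.inf)
    rows = np.arange(test_X.shape[0])[:, None]
    top = np.argsort(-sims, axis=1, kind="stable")[:, :k]
    scores["cos_alpha"] = 1.0 - sims[rows, top].mean(axis=1)
    return NoveltyScores(scores=scores, k=k)
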