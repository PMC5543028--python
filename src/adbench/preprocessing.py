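"""Autoscaling and the distance/similarity primitives used by the AD measures."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

EUCLIDEAN = "euclidean"
TANIMOTO = "tanimoto"
METRICS = (EUCLIDEAN, TANIMOTO)


class ConstantColumnError(ValueError):
    """A descriptor column has zero standard deviation and cannot be autoscaled."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"constant column(s): {self.columns}")


class AutoscaleResult(NamedTuple):
    X_scaled: np.ndarray
    centers: np.ndarray
    scales: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply the fitted centers/scales to new objects."""
        return (np.asarray(X, dtype=float) - self.centers) / self.scales


def autoscale(X: np.ndarray) -> AutoscaleResult:
    """Column-wise mean centering and division by the sample standard deviation.

    The standard deviation uses the n-1 denominator.  Constant columns raise
    :class:`ConstantColumnError` naming the offending column indices; callers
    may drop them and retry.
    """
    X = np.asarray(X, dtype=float)
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(scales == 0.0)
    if bad.size:
        raise ConstantColumnError(bad)
    return AutoscaleResult((X - centers) / scales, centers, scales)


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def tanimoto_distance(a: np.ndarray, b: np.ndarray) -> float:
    """One minus the (continuous) Tanimoto similarity.

    ``1 - a.b / (|a|^2 + |b|^2 - a.b)``.  On 0/1 vectors this is one minus
    |intersection|/|union|; the continuous form also covers substructure
    counts and arbitrary real vectors (the denominator is positive for any
    pair that is not both zero).  Undefined when both vectors are all-zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    ab = float(a @ b)
    denom = float(a @ a) + float(b @ b) - ab
    if denom == 0.0:
        raise ValueError("Tanimoto similarity undefined for two all-zero vectors")
    return 1.0 - ab / denom


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Inner product of the two vectors divided by the product of their lengths."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero-length vector")
    return float(a @ b / (na * nb))


# -- vectorized pairwise forms used by the novelty measures ------------------

def pairwise_distances(queries: np.ndarray, train: np.ndarray, metric: str) -> np.ndarray:
    """Distance matrix (n_query x n_train) under the requested metric."""
    Q = np.asarray(queries, dtype=float)
    T = np.asarray(train, dtype=float)
    if Q.shape[1] != T.shape[1]:
        raise ValueError("query/train dimension mismatch")
    if metric == EUCLIDEAN:
        sq = (Q**2).sum(1)[:, None] + (T**2).sum(1)[None, :] - 2.0 * Q @ T.T
        return np.sqrt(np.maximum(sq, 0.0))
    if metric == TANIMOTO:
        ab = Q @ T.T
        denom = (Q**2).sum(1)[:, None] + (T**2).sum(1)[None, :] - ab
        if (denom == 0.0).any():
            raise ValueError("Tanimoto similarity undefined for two all-zero vectors")
        return 1.0 - ab / denom
    raise ValueError(f"unknown metric {metric!r}")


def pairwise_cosine(queries: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Cosine-similarity matrix (n_query x n_train)."""
    Q = np.asarray(queries, dtype=float)
    T = np.asarray(train, dtype=float)
    nq = np.linalg.norm(Q, axis=1)
    nt = np.linalg.norm(T, axis=1)
    if (nq == 0.0).any() or (nt == 0.0).any():
        raise ValueError("cosine similarity undefined for a zero-length vector")
    return (Q @ T.T) / np.outer(nq, nt)
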