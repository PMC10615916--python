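"""The five sensorimotor distance metrics.

The principal measure is cosine distance, 1 − cos(angle) between two
concepts' 11-dimensional rating vectors; for non-negative ratings it lies
in [0, 1].  Four alternatives are provided: correlation distance
(1 − Pearson r across the 11 dimensions), Euclidean, Minkowski-3, and
Mahalanobis distance, which whitens by the inter-dimension covariance
estimated from a whole norms table.

Scalar functions here are written directly from the definitions; block
computations elsewhere in the package go through
:func:`pairwise_distances` (scipy ``cdist``) and are tested to agree with
these to 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    InsufficientDataError,
    MetricSpecError,
    UndefinedCorrelationError,
    UndefinedDirectionError,
)
from .norms import N_DIMENSIONS, NormsTable, SensorimotorVector

METRIC_NAMES = ("cosine", "correlation", "euclidean", "minkowski3", "mahalanobis")


def _ratings(v) -> np.ndarray:
    if isinstance(v, SensorimotorVector):
        return v.array
    arr = np.asarray(v, dtype=np.float64)
    if arr.shape != (N_DIMENSIONS,):
        raise ValueError(f"expected a length-{N_DIMENSIONS} vector, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class CovarianceContext:
    """Inter-dimension covariance and its (pseudo-)inverse.

    Estimated across all concepts of a norms table (dimensions as
    variables, concepts as observations, unbiased n−1 denominator).
    The pseudo-inverse makes near-singular covariances safe while being
    identical to the plain inverse when well conditioned.
    """

    matrix: np.ndarray
    inverse: np.ndarray
    source_n: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (N_DIMENSIONS, N_DIMENSIONS):
            raise MetricSpecError(f"covariance must be 11×11, got {m.shape}")
        if not np.allclose(m, m.T, atol=1e-8):
            raise MetricSpecError("covariance matrix must be symmetric")


@dataclass(frozen=True)
class MetricSpec:
    """A metric chosen by name, plus the covariance context Mahalanobis needs."""

    kind: str = "cosine"
    context: Optional[CovarianceContext] = None

    def __post_init__(self) -> None:
        if self.kind not in METRIC_NAMES:
            raise MetricSpecError(
                f"unknown metric {self.kind!r}; choose from {METRIC_NAMES}"
            )
        if self.kind == "mahalanobis" and self.context is None:
            raise MetricSpecError(
                "mahalanobis distance requires a CovarianceContext "
                "(see estimate_covariance)"
            )


def cosine_distance(u, v) -> float:
    """1 − (u·v)/(‖u‖‖v‖); in [0, 1] for non-negative vectors.

    Raises
    ------
    UndefinedDirectionError
        If either vector is all zeros (the angle is undefined).
    """
    a, b = _ratings(u), _ratings(v)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedDirectionError(
            "cosine distance is undefined for an all-zero rating vector"
        )
    return float(1.0 - (a @ b) / (na * nb))


def correlation_distance(u, v) -> float:
    """1 − Pearson correlation of the two 11-value sequences."""
    a, b = _ratings(u), _ratings(v)
    ac, bc = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0.0 or nb == 0.0:
        raise UndefinedCorrelationError(
            "correlation distance is undefined for a constant rating vector"
        )
    return float(1.0 - (ac @ bc) / (na * nb))


def euclidean_distance(u, v) -> float:
    a, b = _ratings(u), _ratings(v)
    return float(np.linalg.norm(a - b))


def minkowski3_distance(u, v) -> float:
    a, b = _ratings(u), _ratings(v)
    return float(np.sum(np.abs(a - b) ** 3) ** (1.0 / 3.0))


def mahalanobis_distance(u, v, context: CovarianceContext) -> float:
    a, b = _ratings(u), _ratings(v)
    d = a - b
    q = float(d @ context.inverse @ d)
    # pseudo-inverse quadratic form can go ~-1e-16 for identical vectors
    return float(np.sqrt(max(q, 0.0)))


def metric_distance(u, v, spec: MetricSpec) -> float:
    """Dispatch to the metric named in ``spec``.

    All five are symmetric and zero for identical vectors.
    """
    if spec.kind == "cosine":
        return cosine_distance(u, v)
    if spec.kind == "correlation":
        return correlation_distance(u, v)
    if spec.kind == "euclidean":
        return euclidean_distance(u, v)
    if spec.kind == "minkowski3":
        return minkowski3_distance(u, v)
    assert spec.kind == "mahalanobis" and spec.context is not None
    return mahalanobis_distance(u, v, spec.context)


def estimate_covariance(table: NormsTable) -> CovarianceContext:
    """Estimate the 11×11 inter-dimension covariance from a whole table.

    A single global covariance — one geometry for the whole space — is
    used for Mahalanobis distance, rather than anything pair-local.
    """
    if table.n < 2:
        raise InsufficientDataError(
            f"covariance estimation needs at least 2 concepts, table has {table.n}"
        )
    cov = np.cov(table.matrix, rowvar=False, ddof=1)
    inv = np.linalg.pinv(cov, hermitian=True)
    return CovarianceContext(matrix=cov, inverse=inv, source_n=table.n)


def pairwise_distances(a: np.ndarray, b: np.ndarray, spec: MetricSpec) -> np.ndarray:
    """Block pairwise distance matrix between row sets ``a`` and ``b``.

    Vectorised path used by streaming pair scans, neighbour queries and
    layout code.  Raises the same errors as the scalar functions for
    degenerate rows (all-zero under cosine, constant under correlation).
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if spec.kind == "cosine":
        for block in (a, b):
            if np.any(np.all(block == 0.0, axis=1)):
                raise UndefinedDirectionError(
                    "cosine distance is undefined for an all-zero rating vector"
                )
        d = cdist(a, b, metric="cosine")
    elif spec.kind == "correlation":
        for block in (a, b):
            if np.any(np.ptp(block, axis=1) == 0.0):
                raise UndefinedCorrelationError(
                    "correlation distance is undefined for a constant rating vector"
                )
        d = cdist(a, b, metric="correlation")
    elif spec.kind == "euclidean":
        d = cdist(a, b, metric="euclidean")
    elif spec.kind == "minkowski3":
        d = cdist(a, b, metric="minkowski", p=3)
    else:
        assert spec.context is not None
        # expanded quadratic form: d²_ij = q_a(i) + q_b(j) − 2·a VI bᵀ;
        # clamping before the sqrt keeps pseudo-inverse round-off finite
        vi = spec.context.inverse
        qa = np.einsum("ij,jk,ik->i", a, vi, a)
        qb = np.einsum("ij,jk,ik->i", b, vi, b)
        d2 = qa[:, None] + qb[None, :] - 2.0 * (a @ vi @ b.T)
        d = np.sqrt(np.maximum(d2, 0.0))
    # cdist can produce tiny negative values from cancellation
    return np.maximum(d, 0.0)
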