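"""2-D layouts of selected concepts and polar-profile export.

The layout minimises Sammon stress

    E(Y) = (1/c) · Σ_{i<j} (d*_ij − d_ij)² / d*_ij,   c = Σ_{i<j} d*_ij,

where d* are the input sensorimotor distances and d the Euclidean
distances of the 2-D layout Y.  Minimisation is gradient descent with a
backtracking step size, so the reported stress sequence is non-increasing
by construction.  Initialisation is classical scaling (eigendecomposition
of the doubly centred squared-distance matrix), which is deterministic; a
seeded random configuration is used only when that is degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InsufficientDataError
from .metrics import MetricSpec, pairwise_distances
from .norms import DIMENSIONS, NormsTable, normalize_word

#: Clockwise-from-top dimension order for polar profiles.  This coincides
#: with the canonical table order: six perceptual modalities then five
#: action effectors.
PROFILE_ORDER: tuple[str, ...] = DIMENSIONS

_ZERO_DISTANCE_FLOOR = 1e-9


@dataclass
class EmbeddingLayout:
    """A 2-D configuration for a word list, with its final Sammon stress."""

    words: tuple[str, ...]
    coords: np.ndarray
    stress: float
    seed: int
    iterations: int
    stress_history: tuple[float, ...]


@dataclass(frozen=True)
class ProfileExport:
    """One concept's 11 ratings in polar-plot (clockwise-from-top) order."""

    word: str
    values: tuple[float, ...]

    @property
    def order(self) -> tuple[str, ...]:
        return PROFILE_ORDER


def sammon_stress(target: np.ndarray, coords: np.ndarray) -> float:
    """Sammon stress of a layout against a condensed target-distance vector."""
    d = np.maximum(pdist(coords), 1e-300)
    c = target.sum()
    return float(((target - d) ** 2 / target).sum() / c)


def _sammon_gradient(target_sq: np.ndarray, coords: np.ndarray, c: float) -> np.ndarray:
    d = squareform(pdist(coords))
    np.fill_diagonal(d, 1.0)  # diagonal weight is zeroed below
    w = (d - target_sq) / (target_sq * d)
    np.fill_diagonal(w, 0.0)
    diff = coords[:, None, :] - coords[None, :, :]
    return (2.0 / c) * np.einsum("ij,ijk->ik", w, diff)


def _classical_init(target_sq: np.ndarray) -> np.ndarray | None:
    n = target_sq.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (target_sq**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order[:2]], vecs[:, order[:2]]
    if vals[0] <= 0:
        return None
    coords = vecs * np.sqrt(np.maximum(vals, 0.0))
    # fix the sign convention so the layout is reproducible across BLAS builds
    for axis in range(2):
        col = coords[:, axis]
        pivot = np.argmax(np.abs(col))
        if col[pivot] < 0:
            coords[:, axis] = -col
    return coords


def sammon_layout(
    table: NormsTable,
    words: list[str],
    spec: MetricSpec | None = None,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> EmbeddingLayout:
    """Lay out the given concepts in 2-D by minimising Sammon stress.

    Input distances are the pairwise sensorimotor distances under ``spec``
    (cosine by default); exact-zero input distances are floored at 1e-9 so
    the stress weights stay finite.  Deterministic for a given seed.
    """
    spec = spec or MetricSpec()
    keys = [normalize_word(w) for w in words]
    if len(keys) < 3:
        raise InsufficientDataError("a 2-D layout needs at least 3 words")
    vectors = np.array([table.get_vector(k).array for k in keys])

    full = pairwise_distances(vectors, vectors, spec)
    full = 0.5 * (full + full.T)
    np.fill_diagonal(full, 0.0)
    target = np.maximum(squareform(full, checks=False), _ZERO_DISTANCE_FLOOR)
    target_sq = squareform(target)
    np.fill_diagonal(target_sq, 1.0)  # never used at weight time; avoids 0/0
    c = target.sum()

    rng = np.random.default_rng(seed)
    coords = _classical_init(squareform(target))
    if coords is None:
        coords = rng.normal(scale=target.mean(), size=(len(keys), 2))

    stress = sammon_stress(target, coords)
    history = [stress]
    step = 1.0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        grad = _sammon_gradient(target_sq, coords, c)
        gnorm = float(np.linalg.norm(grad))
        if gnorm == 0.0:
            break
        accepted = False
        trial_step = step
        for _ in range(40):
            candidate = coords - trial_step * grad
            new_stress = sammon_stress(target, candidate)
            if new_stress < stress:
                accepted = True
                break
            trial_step *= 0.5
        if not accepted:
            break
        coords = candidate
        improvement = stress - new_stress
        stress = new_stress
        history.append(stress)
        step = trial_step * 1.5
        if improvement < tol * max(stress, 1e-300):
            break

    return EmbeddingLayout(
        words=tuple(keys),
        coords=coords,
        stress=stress,
        seed=seed,
        iterations=iterations,
        stress_history=tuple(history),
    )


def profile_export(table: NormsTable, word: str) -> ProfileExport:
    """Export one concept's ratings in the polar-plot clockwise order."""
    vec = table.get_vector(word)
    values = tuple(vec[dim] for dim in PROFILE_ORDER)
    return ProfileExport(word=normalize_word(word), values=values)


def profile_to_canonical(profile: ProfileExport) -> tuple[float, ...]:
    """Inverse of :func:`profile_export`'s reordering (a bijection)."""
    by_dim = dict(zip(PROFILE_ORDER, profile.values))
    return tuple(by_dim[dim] for dim in DIMENSIONS)
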