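"""Synthetic norms tables and benchmarks with known ground truth.

Real sensorimotor norms exhibit correlated dimension structure (things
that can be touched can usually be seen; things that can be tasted can
usually be smelled).  The generator emulates this with a latent
multivariate normal draw under a block covariance template — positive
correlation within the six perceptual dimensions, within the five action
dimensions, and weaker correlation across the blocks — mapped onto the
0–5 rating scale and clipped.

Synthetic benchmarks score sampled word pairs as a monotone function of
true cosine similarity plus Gaussian noise, so recovery tests have a
closed-form target: with an affine link the observed correlation
attenuates as r = σ_signal / sqrt(σ_signal² + σ_noise²).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .benchmark import BenchmarkTable
from .errors import MetricSpecError, SmdistError
from .metrics import MetricSpec, pairwise_distances
from .norms import N_DIMENSIONS, NormsTable, SensorimotorVector
from .pairspace import pair_count

#: Perceptual dimensions occupy indices 0–5, action dimensions 6–10.
_PERCEPTUAL = slice(0, 6)
_ACTION = slice(6, 11)

#: Location and scale mapping latent standard-normal ratings onto the 0–5
#: scale; chosen to keep most mass inside the bounds with mild clipping.
LATENT_LOCATION = 2.0
LATENT_SCALE = 1.0


def default_covariance_template() -> np.ndarray:
    """Block correlation template: 0.5 within perceptual, 0.4 within action,
    0.2 across blocks, unit diagonal."""
    cov = np.full((N_DIMENSIONS, N_DIMENSIONS), 0.2)
    cov[_PERCEPTUAL, _PERCEPTUAL] = 0.5
    cov[_ACTION, _ACTION] = 0.4
    np.fill_diagonal(cov, 1.0)
    return cov


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic norms table."""

    n_words: int = 100
    covariance_template: np.ndarray | None = None
    clip: tuple[float, float] = (0.0, 5.0)
    seed: int = 0

    def template(self) -> np.ndarray:
        cov = (default_covariance_template()
               if self.covariance_template is None
               else np.asarray(self.covariance_template, dtype=np.float64))
        if cov.shape != (N_DIMENSIONS, N_DIMENSIONS):
            raise MetricSpecError(f"covariance template must be 11×11, got {cov.shape}")
        if not np.allclose(cov, cov.T):
            raise MetricSpecError("covariance template must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-10:
            raise MetricSpecError("covariance template must be positive semi-definite")
        return cov


@dataclass(frozen=True)
class BenchmarkFixtureSpec:
    """Parameters of a synthetic similarity benchmark."""

    n_pairs: int = 500
    noise_sd: float = 0.1
    link: Callable[[np.ndarray], np.ndarray] | None = None  # default identity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SmdistError("noise_sd must be non-negative")


def generate_norms_fixture(spec: FixtureSpec) -> NormsTable:
    """Draw a synthetic norms table; deterministic under the given seed.

    Latent vectors ~ MVN(0, template) are shifted and scaled onto the
    rating scale, clipped into ``spec.clip``, and labelled w00001, w00002…
    """
    if spec.n_words < 2:
        raise SmdistError("a norms fixture needs at least 2 words")
    cov = spec.template()
    rng = np.random.default_rng(spec.seed)
    latent = rng.multivariate_normal(
        mean=np.zeros(N_DIMENSIONS), cov=cov, size=spec.n_words,
        method="cholesky" if np.linalg.eigvalsh(cov).min() > 1e-10 else "svd",
    )
    lo, hi = spec.clip
    ratings = np.clip(LATENT_LOCATION + LATENT_SCALE * latent, lo, hi)
    width = len(str(spec.n_words))
    vectors = [
        SensorimotorVector(word=f"w{i + 1:0{max(width, 5)}d}",
                           ratings=tuple(row))
        for i, row in enumerate(ratings)
    ]
    return NormsTable(vectors, source=f"synthetic(seed={spec.seed}, n={spec.n_words})")


@dataclass
class SyntheticBenchmark:
    """A generated benchmark plus its generative ground truth."""

    table: BenchmarkTable
    noise_sd: float
    signal_sd: float
    true_similarity: np.ndarray

    @property
    def expected_abs_r(self) -> float:
        """Closed-form attenuated |correlation| against cosine distance
        (exact for an affine link)."""
        if self.signal_sd == 0.0:
            return 0.0
        return self.signal_sd / np.sqrt(self.signal_sd**2 + self.noise_sd**2)


def generate_benchmark_fixture(
    table: NormsTable, spec: BenchmarkFixtureSpec
) -> SyntheticBenchmark:
    """Sample unordered word pairs and score them from true cosine similarity.

    human_score = link(1 − cosine_distance) + Normal(0, noise_sd); the link
    defaults to identity.  Pairs are sampled without replacement.
    """
    n = table.n
    total = pair_count(n)
    if spec.n_pairs > total:
        raise SmdistError(
            f"requested {spec.n_pairs} pairs but only {total} distinct "
            f"unordered pairs exist"
        )
    rng = np.random.default_rng(spec.seed)
    flat = np.sort(rng.choice(total, size=spec.n_pairs, replace=False))
    # decode flat pair index k into (i, j), i < j, row-major over the
    # upper triangle: row i owns indices [offset_i, offset_i + n-1-i)
    rows = np.arange(n, dtype=np.int64)
    offsets = rows * (2 * n - rows - 1) // 2
    ii = np.searchsorted(offsets, flat, side="right") - 1
    jj = ii + 1 + (flat - offsets[ii])

    words = table.words
    x = table.matrix
    dist = np.array([
        pairwise_distances(x[i][None, :], x[j][None, :], MetricSpec("cosine"))[0, 0]
        for i, j in zip(ii, jj)
    ])
    similarity = 1.0 - dist
    link = spec.link or (lambda s: s)
    signal = np.asarray(link(similarity), dtype=np.float64)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_pairs)
    scores = signal + noise

    frame = pd.DataFrame({
        "word1": [words[i] for i in ii],
        "word2": [words[j] for j in jj],
        "score": scores,
    })
    bench = BenchmarkTable(name=f"synthetic(seed={spec.seed})", frame=frame)
    return SyntheticBenchmark(
        table=bench,
        noise_sd=spec.noise_sd,
        signal_sd=float(np.std(signal, ddof=1)) if spec.n_pairs > 1 else 0.0,
        true_similarity=similarity,
    )


def write_benchmark(bench: BenchmarkTable, path) -> None:
    """Write a benchmark in the generic ``word1,word2,score`` layout."""
    bench.frame[["word1", "word2", "score"]].to_csv(
        path, index=False, lineterminator="\n"
    )
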