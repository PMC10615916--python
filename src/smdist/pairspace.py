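"""Streaming statistics over all unordered concept pairs.

At full published-norms scale there are n(n−1)/2 ≈ 788 million pairs, far
too many to materialise.  This module scans the pair space in row blocks,
keeping only running moments (a compensated, mergeable mean/variance
accumulator), bounded lists of the most extreme pairs, and a histogram.
Results are exactly independent of the block size up to floating-point
round-off (tested at 1e-10).

Cosine distances get a fixed 100-bin histogram on [0, 1] (bin width 0.01).
Other metrics have no fixed natural range, so their histogram uses 100
equal bins from 0 to the observed maximum, which requires a second
streaming pass once the maximum is known; nothing is ever materialised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

from .errors import InsufficientDataError, SmdistError
from .metrics import MetricSpec, pairwise_distances
from .norms import NormsTable, normalize_word

DEFAULT_TOP_K = 100
DEFAULT_CHUNK_SIZE = 256
HISTOGRAM_BINS = 100


def pair_count(n: int) -> int:
    """Number of unordered distinct pairs among ``n`` concepts: n(n−1)/2.

    Pure integer arithmetic — exact at any vocabulary size.
    """
    n = int(n)
    if n < 0:
        raise ValueError(f"concept count must be non-negative, got {n}")
    return n * (n - 1) // 2


@dataclass(frozen=True)
class PairDistance:
    """One unordered pair and its distance; word_a < word_b lexicographically."""

    word_a: str
    word_b: str
    metric: str
    value: float

    @staticmethod
    def make(w1: str, w2: str, metric: str, value: float) -> "PairDistance":
        a, b = sorted((w1, w2))
        return PairDistance(word_a=a, word_b=b, metric=metric, value=float(value))


@dataclass
class DistanceSummary:
    """Distribution summary of one metric over all unordered pairs."""

    metric: str
    n_concepts: int
    n_pairs: int
    mean: float
    sd: float
    min_pairs: list[PairDistance]
    max_pairs: list[PairDistance]
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    top_k: int

    @property
    def min_value(self) -> float:
        return self.min_pairs[0].value

    @property
    def max_value(self) -> float:
        return self.max_pairs[0].value

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "n_concepts": self.n_concepts,
            "n_pairs": self.n_pairs,
            "mean": self.mean,
            "sd": self.sd,
            "min_pairs": [vars(p) for p in self.min_pairs],
            "max_pairs": [vars(p) for p in self.max_pairs],
            "histogram": {
                "bin_edges": [float(e) for e in self.bin_edges],
                "counts": [int(c) for c in self.bin_counts],
            },
            "top_k": self.top_k,
        }


@dataclass
class NeighbourResult:
    """Ranked nearest neighbours of one query concept."""

    query: str
    k: int
    metric: str
    neighbours: list[tuple[str, float]]


class _Moments:
    """Mergeable running mean / M2 (Chan et al. parallel update)."""

    __slots__ = ("n", "mean", "m2")

    def __init__(self) -> None:
        self.n = 0
        self.mean = 0.0
        self.m2 = 0.0

    def add_block(self, values: np.ndarray) -> None:
        nb = values.size
        if nb == 0:
            return
        mb = float(values.mean())
        m2b = float(((values - mb) ** 2).sum())
        if self.n == 0:
            self.n, self.mean, self.m2 = nb, mb, m2b
            return
        delta = mb - self.mean
        total = self.n + nb
        self.m2 += m2b + delta * delta * self.n * nb / total
        self.mean += delta * nb / total
        self.n = total

    @property
    def sd(self) -> float:
        if self.n < 2:
            return 0.0
        return float(np.sqrt(self.m2 / (self.n - 1)))


def _block_pairs(
    table: NormsTable, spec: MetricSpec, chunk_size: int
) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Yield (values, i_indices, j_indices) for successive row blocks,
    covering each unordered pair with i < j exactly once."""
    x = table.matrix
    n = table.n
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        d = pairwise_distances(x[start:stop], x[start:], spec)
        rows, cols = np.triu_indices(stop - start, k=1, m=n - start)
        # keep only j > i: local col index must exceed local row index
        yield d[rows, cols], rows + start, cols + start


def _merge_extremes(
    pool: list[tuple[float, str, str]],
    candidates: list[tuple[float, str, str]],
    k: int,
    largest: bool,
) -> list[tuple[float, str, str]]:
    pool.extend(candidates)
    pool.sort(key=(lambda t: (-t[0], t[1], t[2])) if largest else None)
    del pool[k:]
    return pool


def summarize_distances(
    table: NormsTable,
    spec: MetricSpec | None = None,
    top_k: int = DEFAULT_TOP_K,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> DistanceSummary:
    """Scan every unordered concept pair and summarise the distribution.

    Returns running mean and (sample) SD, the ``top_k`` smallest and
    largest pairs (ties broken lexicographically), and a histogram.
    Self-pairs are excluded throughout.
    """
    spec = spec or MetricSpec()
    if table.n < 2:
        raise InsufficientDataError("pair summary needs at least 2 concepts")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")

    words = table.words
    moments = _Moments()
    smallest: list[tuple[float, str, str]] = []
    largest: list[tuple[float, str, str]] = []
    counts = np.zeros(HISTOGRAM_BINS, dtype=np.int64)
    cosine_edges = np.linspace(0.0, 1.0, HISTOGRAM_BINS + 1)

    for values, ii, jj in _block_pairs(table, spec, chunk_size):
        moments.add_block(values)
        kk = min(top_k, values.size)
        for pick_largest, pool in ((False, smallest), (True, largest)):
            order = np.argpartition(-values if pick_largest else values, kk - 1)[:kk]
            cand = [
                (float(values[t]), *sorted((words[ii[t]], words[jj[t]])))
                for t in order
            ]
            _merge_extremes(pool, cand, top_k, pick_largest)
        if spec.kind == "cosine":
            counts += np.histogram(np.clip(values, 0.0, 1.0), bins=cosine_edges)[0]

    if spec.kind == "cosine":
        edges = cosine_edges
    else:
        observed_max = largest[0][0]
        edges = np.linspace(0.0, observed_max if observed_max > 0 else 1.0,
                            HISTOGRAM_BINS + 1)
        for values, _, _ in _block_pairs(table, spec, chunk_size):
            counts += np.histogram(np.clip(values, edges[0], edges[-1]), bins=edges)[0]

    return DistanceSummary(
        metric=spec.kind,
        n_concepts=table.n,
        n_pairs=pair_count(table.n),
        mean=moments.mean,
        sd=moments.sd,
        min_pairs=[PairDistance(a, b, spec.kind, v) for v, a, b in smallest],
        max_pairs=[PairDistance(a, b, spec.kind, v) for v, a, b in largest],
        bin_edges=edges,
        bin_counts=counts,
        top_k=top_k,
    )


def extreme_pairs(
    summary: DistanceSummary,
    which: Literal["smallest", "largest"],
    k: int,
) -> list[PairDistance]:
    """The ``k`` most extreme retained pairs from a summary."""
    if which not in ("smallest", "largest"):
        raise ValueError(f"which must be 'smallest' or 'largest', got {which!r}")
    pool = summary.min_pairs if which == "smallest" else summary.max_pairs
    retained = min(summary.top_k, summary.n_pairs)
    if k > retained:
        raise SmdistError(
            f"requested {k} extreme pairs but only {retained} were retained "
            f"(top_k={summary.top_k})"
        )
    return pool[:k]


def nearest_neighbours(
    table: NormsTable,
    word: str,
    k: int,
    spec: MetricSpec | None = None,
) -> NeighbourResult:
    """Exact k-nearest-neighbour scan for one query concept.

    Distances to every other concept are computed and the smallest ``k``
    returned in ascending order, ties broken alphabetically; the query
    itself is excluded and ``k`` is capped at n−1.
    """
    spec = spec or MetricSpec()
    if k < 1:
        raise ValueError("k must be >= 1")
    vec = table.get_vector(word)
    key = normalize_word(word)
    d = pairwise_distances(vec.array[None, :], table.matrix, spec)[0]
    words = table.words
    ranked = sorted(
        ((float(d[i]), w) for i, w in enumerate(words) if w != key),
        key=lambda t: (t[0], t[1]),
    )
    kk = min(k, table.n - 1)
    return NeighbourResult(
        query=key,
        k=k,
        metric=spec.kind,
        neighbours=[(w, v) for v, w in ranked[:kk]],
    )
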