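import numpy as np
import pytest

from smdist import (
    BenchmarkFixtureSpec,
    FixtureSpec,
    NormsTable,
    SensorimotorVector,
    generate_benchmark_fixture,
    generate_norms_fixture,
)


def table_from_matrix(matrix, words=None, source="<test>") -> NormsTable:
    """Build a NormsTable directly from an (n, 11) array of ratings."""
    matrix = np.asarray(matrix, dtype=float)
    if words is None:
        words = [f"t{i:04d}" for i in range(len(matrix))]
    return NormsTable(
        [SensorimotorVector(word=w, ratings=tuple(row))
         for w, row in zip(words, matrix)],
        source=source,
    )


def random_ratings(rng, n, zero_safe=True):
    """(n, 11) ratings in [0, 5]; rows guaranteed non-zero/non-constant."""
    x = rng.uniform(0.0, 5.0, size=(n, 11))
    if zero_safe:
        # nudge degenerate rows: all-zero or constant rows break cosine /
        # correlation by design, which these helpers are not testing
        x[:, 0] += 0.01
        x[:, 1] += 0.02
    return x


@pytest.fixture(scope="session")
def small_table() -> NormsTable:
    """100-word correlated synthetic norms table (deterministic)."""
    return generate_norms_fixture(FixtureSpec(n_words=100, seed=11))


@pytest.fixture(scope="session")
def mid_table() -> NormsTable:
    """200-word table for neighbour-oracle tests."""
    return generate_norms_fixture(FixtureSpec(n_words=200, seed=12))


@pytest.fixture(scope="session")
def noiseless_benchmark(small_table):
    return generate_benchmark_fixture(
        small_table, BenchmarkFixtureSpec(n_pairs=400, noise_sd=0.0, seed=5)
    )
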