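"""Benchmark loading, coverage, correlations, ΔR² and concreteness splits."""

import numpy as np
import pandas as pd
import pytest

from smdist import (
    BenchmarkTable,
    ConcretenessMap,
    MetricSpec,
    attach_distance,
    attach_predictors,
    best_subset,
    concreteness_split,
    correlate,
    evaluate,
    hierarchical_delta_r2,
    load_benchmark,
)
from smdist.benchmark import DISTANCE_COLUMN
from smdist.errors import (
    DuplicatePairError,
    InsufficientDataError,
    ParseError,
    SchemaError,
    UndefinedCorrelationError,
)


def _generic_frame(n=10, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "word1": [f"a{i}" for i in range(n)],
        "word2": [f"b{i}" for i in range(n)],
        "score": rng.uniform(0, 10, n).round(3),
    })


class TestLoadBenchmark:
    def test_generic_dialect(self, tmp_path):
        path = tmp_path / "bench.csv"
        _generic_frame(10).to_csv(path, index=False)
        bench = load_benchmark(path, dialect="generic")
        assert bench.n_pairs == 10
        assert list(bench.frame.columns) == ["word1", "word2", "score"]

    def test_words_are_normalised(self, tmp_path):
        frame = pd.DataFrame(
            {"word1": ["  Old   TIMER "], "word2": ["CLOCK"], "score": [7.5]}
        )
        path = tmp_path / "bench.csv"
        frame.to_csv(path, index=False)
        bench = load_benchmark(path)
        assert bench.frame.loc[0, "word1"] == "old timer"
        assert bench.frame.loc[0, "word2"] == "clock"

    def test_duplicate_unordered_pair_rejected(self, tmp_path):
        frame = pd.DataFrame({
            "word1": ["cat", "dog"],
            "word2": ["dog", "CAT"],
            "score": [5.0, 6.0],
        })
        path = tmp_path / "dup.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(DuplicatePairError):
            load_benchmark(path)

    def test_simlex_dialect(self, tmp_path):
        frame = pd.DataFrame({
            "word1": ["old", "smart"],
            "word2": ["new", "intelligent"],
            "POS": ["A", "A"],
            "SimLex999": ["1.58", "9.2"],
        })
        path = tmp_path / "simlex.txt"
        frame.to_csv(path, sep="\t", index=False)
        bench = load_benchmark(path, dialect="simlex")
        assert bench.n_pairs == 2
        assert bench.frame.loc[1, "score"] == 9.2

    def test_wordsim_dialect(self, tmp_path):
        path = tmp_path / "combined.csv"
        path.write_text(
            "Word 1,Word 2,Human (mean)\nlove,sex,6.77\ntiger,cat,7.35\n"
        )
        bench = load_benchmark(path, dialect="wordsim")
        assert bench.n_pairs == 2

    def test_men_dialect(self, tmp_path):
        path = tmp_path / "men.txt"
        path.write_text("sun sunlight 50.0\nriver water 49.0\n\n")
        bench = load_benchmark(path, dialect="men")
        assert bench.n_pairs == 2
        assert bench.frame.loc[0, "score"] == 50.0

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "men.txt"
        path.write_text("sun sunlight 50.0\nriver water\n")
        with pytest.raises(ParseError, match="line 2"):
            load_benchmark(path, dialect="men")

    def test_missing_score_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"word1": ["a"], "word2": ["b"]}).to_csv(path, index=False)
        with pytest.raises(SchemaError):
            load_benchmark(path)


class TestAttachDistance:
    def test_full_coverage(self, small_table, noiseless_benchmark):
        bench, covered = attach_distance(noiseless_benchmark.table, small_table)
        assert covered == bench.n_pairs
        assert bench.frame["covered"].all()

    def test_missing_word_reduces_coverage_but_keeps_pair(self, small_table,
                                                          noiseless_benchmark):
        frame = noiseless_benchmark.table.frame.copy()
        frame.loc[0, "word1"] = "unknown concept"
        bench = BenchmarkTable(name="edited", frame=frame)
        bench, covered = attach_distance(bench, small_table)
        assert covered == bench.n_pairs - 1
        assert bench.n_pairs == len(frame)
        assert np.isnan(bench.frame.loc[0, DISTANCE_COLUMN])

    def test_distances_match_direct_metric(self, small_table, noiseless_benchmark):
        spec = MetricSpec("cosine")
        bench, _ = attach_distance(noiseless_benchmark.table, small_table, spec)
        row = bench.frame.iloc[3]
        from smdist import metric_distance

        direct = metric_distance(
            small_table.get_vector(row.word1), small_table.get_vector(row.word2),
            spec,
        )
        assert row[DISTANCE_COLUMN] == pytest.approx(direct, abs=1e-12)


class TestCorrelate:
    def test_identity_column_gives_r_one(self):
        frame = _generic_frame(20, seed=1)
        frame["copy"] = frame["score"]
        bench = BenchmarkTable(name="t", frame=frame)
        r, n = correlate(bench, "copy")
        assert r == pytest.approx(1.0, abs=1e-12)
        assert n == 20

    def test_negated_column_gives_r_minus_one(self):
        frame = _generic_frame(20, seed=2)
        frame["neg"] = -frame["score"]
        bench = BenchmarkTable(name="t", frame=frame)
        r, _ = correlate(bench, "neg")
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_invariant_to_increasing_linear_rescale(self):
        frame = _generic_frame(50, seed=3)
        rng = np.random.default_rng(4)
        frame["pred"] = frame["score"] * 0.5 + rng.normal(0, 1, 50)
        bench = BenchmarkTable(name="t", frame=frame)
        r0, _ = correlate(bench, "pred")
        frame2 = frame.copy()
        frame2["score"] = 3.0 + 11.0 * frame2["score"]
        frame2["pred"] = -2.0 + 0.25 * frame2["pred"]
        r1, _ = correlate(BenchmarkTable(name="t2", frame=frame2), "pred")
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_constant_column_rejected(self):
        frame = _generic_frame(10, seed=5)
        frame["flat"] = 1.0
        with pytest.raises(UndefinedCorrelationError):
            correlate(BenchmarkTable(name="t", frame=frame), "flat")

    def test_missing_rows_dropped_listwise(self):
        frame = _generic_frame(10, seed=6)
        frame["pred"] = frame["score"]
        frame.loc[[1, 4], "pred"] = np.nan
        _, n = correlate(BenchmarkTable(name="t", frame=frame), "pred")
        assert n == 8

    def test_too_few_rows(self):
        frame = _generic_frame(2, seed=7)
        frame["pred"] = [1.0, 2.0]
        with pytest.raises(InsufficientDataError):
            correlate(BenchmarkTable(name="t", frame=frame), "pred")


class TestHierarchicalDeltaR2:
    def test_duplicated_predictor_gives_zero_delta(self, small_table,
                                                   noiseless_benchmark):
        bench, _ = attach_distance(noiseless_benchmark.table, small_table)
        r2_1, r2_2, delta = hierarchical_delta_r2(bench, step1=DISTANCE_COLUMN)
        assert delta == 0.0
        assert r2_1 == pytest.approx(r2_2, abs=1e-12)

    def test_noise_step1_with_exact_negative_score(self, small_table,
                                                   noiseless_benchmark):
        bench, _ = attach_distance(noiseless_benchmark.table, small_table)
        rng = np.random.default_rng(8)
        frame = bench.frame.copy()
        frame["score"] = -frame[DISTANCE_COLUMN]
        frame["junk"] = rng.normal(size=len(frame))
        bench = BenchmarkTable(name="forced", frame=frame)
        r2_1, r2_2, delta = hierarchical_delta_r2(bench, step1="junk")
        assert r2_2 == pytest.approx(1.0, abs=1e-10)
        assert delta == pytest.approx(1.0 - r2_1, abs=1e-10)

    def test_delta_r2_non_negative_for_random_predictors(self, small_table,
                                                         noiseless_benchmark):
        bench, _ = attach_distance(noiseless_benchmark.table, small_table)
        rng = np.random.default_rng(9)
        frame = bench.frame.copy()
        for i in range(5):
            frame[f"p{i}"] = rng.normal(size=len(frame))
        bench = BenchmarkTable(name="many", frame=frame)
        for i in range(5):
            _, _, delta = hierarchical_delta_r2(bench, step1=f"p{i}")
            assert delta >= 0.0

    def test_r2_matches_normal_equations_oracle(self):
        """OLS R² values agree with an independent lstsq solve."""
        rng = np.random.default_rng(10)
        n = 20
        frame = pd.DataFrame({
            "word1": [f"a{i}" for i in range(n)],
            "word2": [f"b{i}" for i in range(n)],
            "score": rng.normal(size=n),
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
        })
        bench = BenchmarkTable(name="t", frame=frame)
        r2_1, r2_2, delta = hierarchical_delta_r2(bench, step1="x1", step2="x2")

        def oracle_r2(y, *cols):
            x = np.column_stack([np.ones(len(y)), *cols])
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta
            return 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

        y = frame["score"].to_numpy()
        assert r2_1 == pytest.approx(oracle_r2(y, frame["x1"]), abs=1e-10)
        assert r2_2 == pytest.approx(oracle_r2(y, frame["x1"], frame["x2"]),
                                     abs=1e-10)
        assert delta == pytest.approx(r2_2 - r2_1, abs=1e-12)

    def test_collinear_predictors_rejected(self):
        frame = _generic_frame(10, seed=11)
        frame["x1"] = np.arange(10.0)
        frame["x2"] = 2.0 * frame["x1"] + 1.0
        bench = BenchmarkTable(name="t", frame=frame)
        with pytest.raises(InsufficientDataError):
            hierarchical_delta_r2(bench, step1="x1", step2="x2")


class TestBestSubset:
    def test_perfect_predictor_wins(self):
        frame = _generic_frame(50, seed=12)
        rng = np.random.default_rng(13)
        frame["perfect"] = frame["score"]
        frame["noise"] = rng.normal(size=50)
        bench = BenchmarkTable(name="t", frame=frame)
        fits = best_subset(bench, ["perfect", "noise"])
        assert fits[0].predictors == ("perfect",)
        assert fits[0].r2 == pytest.approx(1.0, abs=1e-10)

    def test_enumeration_count(self):
        frame = _generic_frame(60, seed=14)
        rng = np.random.default_rng(15)
        names = [f"p{i}" for i in range(4)]
        for name in names:
            frame[name] = rng.normal(size=60)
        fits = best_subset(BenchmarkTable(name="t", frame=frame), names)
        assert len(fits) == 2**4 - 1

    def test_pure_noise_predictor_never_helps(self, small_table):
        """Adding an irrelevant predictor does not displace the true model."""
        from smdist import BenchmarkFixtureSpec, generate_benchmark_fixture

        synth = generate_benchmark_fixture(
            small_table, BenchmarkFixtureSpec(n_pairs=500, noise_sd=0.05, seed=16)
        )
        bench, _ = attach_distance(synth.table, small_table)
        rng = np.random.default_rng(17)
        frame = bench.frame.copy()
        frame["pure_noise"] = rng.normal(size=len(frame))
        bench = BenchmarkTable(name="t", frame=frame)
        fits = best_subset(bench, [DISTANCE_COLUMN, "pure_noise"])
        assert fits[0].predictors == (DISTANCE_COLUMN,)


class TestConcretenessSplit:
    @pytest.fixture
    def cmap(self):
        return ConcretenessMap(ratings={
            "ghost": 2.1, "spirit": 2.9, "rock": 3.0, "stone": 4.5,
            "idea": 1.5,
        })

    def _bench(self, pairs):
        frame = pd.DataFrame(
            [(w1, w2, 5.0 + i) for i, (w1, w2) in enumerate(pairs)],
            columns=["word1", "word2", "score"],
        )
        return BenchmarkTable(name="t", frame=frame)

    def test_both_below_threshold_is_abstract(self, cmap):
        parts = concreteness_split(self._bench([("ghost", "spirit")]), cmap)
        assert parts["abstract"].n_pairs == 1

    def test_boundary_three_is_concrete(self, cmap):
        """3.0 falls on the concrete side of the < 3 / ≥ 3 rule."""
        parts = concreteness_split(self._bench([("rock", "spirit")]), cmap)
        assert parts["mixed"].n_pairs == 1
        parts = concreteness_split(self._bench([("rock", "stone")]), cmap)
        assert parts["concrete"].n_pairs == 1

    def test_missing_rating_goes_to_unsplit(self, cmap):
        parts = concreteness_split(self._bench([("rock", "mystery")]), cmap)
        assert parts["unsplit"].n_pairs == 1

    def test_partition_is_complete(self, cmap):
        bench = self._bench([
            ("ghost", "idea"), ("rock", "stone"), ("ghost", "rock"),
            ("idea", "nothing"),
        ])
        parts = concreteness_split(bench, cmap)
        assert sum(p.n_pairs for p in parts.values()) == bench.n_pairs


class TestAttachPredictorsAndEvaluate:
    def test_predictors_merge_on_unordered_pair(self, tmp_path):
        frame = _generic_frame(4, seed=18)
        bench = BenchmarkTable(name="t", frame=frame)
        joins = pd.DataFrame({
            # reversed word order must still match
            "word1": frame["word2"],
            "word2": frame["word1"],
            "external": [1.0, 2.0, 3.0, 4.0],
        })
        path = tmp_path / "pred.csv"
        joins.to_csv(path, index=False)
        merged = attach_predictors(bench, path)
        assert list(merged.frame["external"]) == [1.0, 2.0, 3.0, 4.0]

    def test_evaluate_composes_whole_pipeline(self, small_table,
                                              noiseless_benchmark, tmp_path):
        rng = np.random.default_rng(19)
        table = noiseless_benchmark.table
        joins = pd.DataFrame({
            "word1": table.frame["word1"],
            "word2": table.frame["word2"],
            "alt_measure": rng.normal(size=table.n_pairs),
        })
        path = tmp_path / "pred.csv"
        joins.to_csv(path, index=False)
        cmap = ConcretenessMap(ratings={
            w: (2.0 if i % 2 else 4.0) for i, w in enumerate(small_table.words)
        })
        report = evaluate(table, small_table, predictors_path=path,
                          concreteness=cmap)
        assert report.coverage[DISTANCE_COLUMN] == table.n_pairs
        r, n = report.correlations[DISTANCE_COLUMN]
        assert r == pytest.approx(-1.0, abs=1e-9)
        assert all(entry["delta"] >= 0 for entry in report.delta_r2)
        assert report.split_sizes is not None
        assert sum(report.split_sizes.values()) == table.n_pairs
        # serialisable
        import json

        json.dumps(report.to_dict())
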