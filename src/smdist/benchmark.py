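"""Validation against human similarity judgements.

Benchmarks are lists of word pairs with a human similarity score
(SimLex-999, WordSim-353, MEN, or any generic ``word1,word2,score`` file).
Sensorimotor distance is attached to each pair from a norms table; pairs
with either word missing from the norms are flagged uncovered, never
dropped, so coverage is always reportable.  External similarity measures
(e.g. taxonomic distance, feature overlap, distributional distance) arrive
as pre-computed predictor columns and are merged on the normalised
unordered pair.

The evaluation surface mirrors the standard validation pipeline:

* zero-order Pearson correlations between human scores and each predictor
  (human scores are similarities, distances correlate negatively);
* hierarchical regression: R² of an alternative predictor alone (step 1)
  versus that predictor plus sensorimotor distance (step 2), whose
  difference ΔR² is the unique variance sensorimotor distance explains
  (non-negative by construction of nested OLS fits);
* exhaustive best-subset model search ranked by BIC;
* a concreteness split: pairs partitioned into abstract–abstract, mixed,
  and concrete–concrete using a 1–5 concreteness rating with the scale
  midpoint 3 as threshold (< 3 abstract, ≥ 3 concrete).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    DuplicatePairError,
    InsufficientDataError,
    ParseError,
    SchemaError,
    UndefinedCorrelationError,
)
from .metrics import MetricSpec, pairwise_distances
from .norms import NormsTable, normalize_word

DISTANCE_COLUMN = "sensorimotor_distance"
DIALECTS = ("simlex", "wordsim", "men", "generic")
CONCRETENESS_THRESHOLD = 3.0


@dataclass
class BenchmarkTable:
    """Word pairs + human similarity scores (+ optional predictor columns).

    ``frame`` columns: word1, word2 (normalised keys), score, then any
    predictor columns.  The unordered pair (min, max of the two keys) is
    unique within a benchmark.
    """

    name: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("word1", "word2", "score"):
            if col not in self.frame.columns:
                raise SchemaError(f"benchmark frame missing column {col!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.frame)

    @property
    def predictor_columns(self) -> tuple[str, ...]:
        return tuple(
            c for c in self.frame.columns
            if c not in ("word1", "word2", "score", "covered")
        )

    def pair_keys(self) -> pd.Series:
        lo = self.frame[["word1", "word2"]].min(axis=1)
        hi = self.frame[["word1", "word2"]].max(axis=1)
        return lo + "␟" + hi  # unit-separator join; words never contain it


@dataclass(frozen=True)
class ConcretenessMap:
    """word key → concreteness rating (1–5); split threshold default 3."""

    ratings: dict[str, float]
    threshold: float = CONCRETENESS_THRESHOLD

    def category(self, word: str) -> str | None:
        rating = self.ratings.get(normalize_word(word))
        if rating is None:
            return None
        return "abstract" if rating < self.threshold else "concrete"


@dataclass
class SubsetFit:
    predictors: tuple[str, ...]
    r2: float
    bic: float
    n: int


@dataclass
class EvalReport:
    """Full evaluation output for one benchmark."""

    benchmark: str
    metric: str
    coverage: dict[str, int]
    correlations: dict[str, tuple[float, int]]
    delta_r2: list[dict]
    best_subset: list[SubsetFit]
    splits: dict[str, tuple[float, int]] | None = None
    split_sizes: dict[str, int] | None = None

    def to_dict(self) -> dict:
        return {
            "benchmark": self.benchmark,
            "metric": self.metric,
            "coverage": self.coverage,
            "correlations": {
                k: {"r": r, "n": n} for k, (r, n) in self.correlations.items()
            },
            "delta_r2": self.delta_r2,
            "best_subset": [vars(s) | {"predictors": list(s.predictors)}
                            for s in self.best_subset],
            "splits": None if self.splits is None else {
                k: {"r": r, "n": n} for k, (r, n) in self.splits.items()
            },
            "split_sizes": self.split_sizes,
        }


def _finish_benchmark(name: str, rows: list[tuple[str, str, float]],
                      source: str) -> BenchmarkTable:
    frame = pd.DataFrame(rows, columns=["word1", "word2", "score"])
    keys = frame[["word1", "word2"]].min(axis=1) + "␟" + \
        frame[["word1", "word2"]].max(axis=1)
    dup = keys.duplicated(keep=False)
    if dup.any():
        first = frame[dup].iloc[0]
        raise DuplicatePairError(
            f"{source}: duplicate unordered pair "
            f"({first.word1!r}, {first.word2!r})"
        )
    return BenchmarkTable(name=name, frame=frame)


def load_benchmark(path: str | Path, dialect: str = "generic") -> BenchmarkTable:
    """Parse a benchmark file into the common pair table.

    Dialects
    --------
    simlex
        Tab-separated with header; uses columns word1, word2, SimLex999.
    wordsim
        Comma-separated with header "Word 1", "Word 2", "Human (mean)".
    men
        Whitespace-separated ``word1 word2 score`` lines, no header.
    generic
        CSV/TSV (by extension) with header columns word1, word2, score.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")

    def parse_rows(frame: pd.DataFrame, w1: str, w2: str, score: str
                   ) -> list[tuple[str, str, float]]:
        for col in (w1, w2, score):
            if col not in frame.columns:
                raise SchemaError(f"{path}: missing column {col!r}")
        rows = []
        for line, rec in enumerate(frame.itertuples(index=False), start=2):
            rec = dict(zip(frame.columns, rec))
            try:
                rows.append((normalize_word(rec[w1]), normalize_word(rec[w2]),
                             float(rec[score])))
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}: line {line}: {exc}") from None
        return rows

    if dialect == "simlex":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        rows = parse_rows(frame, "word1", "word2", "SimLex999")
    elif dialect == "wordsim":
        frame = pd.read_csv(path, sep=",", dtype=str)
        rows = parse_rows(frame, "Word 1", "Word 2", "Human (mean)")
    elif dialect == "men":
        rows = []
        with open(path, encoding="utf-8") as handle:
            for line_no, line in enumerate(handle, start=1):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise ParseError(
                        f"{path}: line {line_no}: expected 'word1 word2 score', "
                        f"got {line.strip()!r}"
                    )
                try:
                    rows.append((normalize_word(parts[0]),
                                 normalize_word(parts[1]), float(parts[2])))
                except ValueError as exc:
                    raise ParseError(f"{path}: line {line_no}: {exc}") from None
    else:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        frame = pd.read_csv(path, sep=sep, dtype=str)
        rows = parse_rows(frame, "word1", "word2", "score")

    return _finish_benchmark(dialect if dialect != "generic" else path.stem,
                             rows, str(path))


def attach_distance(
    bench: BenchmarkTable,
    table: NormsTable,
    spec: MetricSpec | None = None,
    column: str = DISTANCE_COLUMN,
) -> tuple[BenchmarkTable, int]:
    """Add a sensorimotor-distance column; return (table, covered count).

    Pairs with either word absent from the norms get NaN in the distance
    column and False in ``covered``; they are kept, not dropped.
    """
    spec = spec or MetricSpec()
    frame = bench.frame.copy()
    values = np.full(len(frame), np.nan)
    covered = np.zeros(len(frame), dtype=bool)
    for i, (w1, w2) in enumerate(zip(frame["word1"], frame["word2"])):
        if w1 in table and w2 in table:
            d = pairwise_distances(
                table.get_vector(w1).array[None, :],
                table.get_vector(w2).array[None, :],
                spec,
            )[0, 0]
            values[i] = d
            covered[i] = True
    frame[column] = values
    frame["covered"] = covered
    return BenchmarkTable(name=bench.name, frame=frame), int(covered.sum())


def attach_predictors(bench: BenchmarkTable, path: str | Path) -> BenchmarkTable:
    """Merge extra predictor columns from a delimited join file.

    The file has header ``word1, word2, predictor...``; rows are matched on
    the normalised unordered pair, so word order need not agree.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    joins = pd.read_csv(path, sep=sep)
    for col in ("word1", "word2"):
        if col not in joins.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
        joins[col] = joins[col].map(normalize_word)
    joins["_pair"] = joins[["word1", "word2"]].min(axis=1) + "␟" + \
        joins[["word1", "word2"]].max(axis=1)
    joins = joins.drop(columns=["word1", "word2"]).set_index("_pair")
    if joins.index.duplicated().any():
        raise DuplicatePairError(f"{path}: duplicate unordered pair in join file")

    frame = bench.frame.copy()
    frame["_pair"] = bench.pair_keys()
    merged = frame.merge(joins, how="left", left_on="_pair", right_index=True)
    merged = merged.drop(columns=["_pair"])
    return BenchmarkTable(name=bench.name, frame=merged)


def load_concreteness(path: str | Path, word_column: str = "Word",
                      rating_column: str = "Conc.M",
                      threshold: float = CONCRETENESS_THRESHOLD) -> ConcretenessMap:
    """Read a word → concreteness-rating table (published header by default)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep)
    for col in (word_column, rating_column):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    ratings = {
        normalize_word(w): float(r)
        for w, r in zip(frame[word_column], frame[rating_column])
        if isinstance(w, str) and w.strip()
    }
    return ConcretenessMap(ratings=ratings, threshold=threshold)


def _joint_rows(bench: BenchmarkTable, columns: list[str]) -> pd.DataFrame:
    cols = list(dict.fromkeys(["score", *columns]))
    return bench.frame[cols].dropna()


def correlate(bench: BenchmarkTable, column: str) -> tuple[float, int]:
    """Pearson r between human scores and one predictor column.

    Computed over jointly non-missing rows; returns (r, n).
    """
    if column not in bench.frame.columns:
        raise SchemaError(f"benchmark has no column {column!r}")
    rows = _joint_rows(bench, [column])
    if len(rows) < 3:
        raise InsufficientDataError(
            f"correlation needs >= 3 jointly covered rows, got {len(rows)}"
        )
    for name in ("score", column):
        if rows[name].nunique() < 2:
            raise UndefinedCorrelationError(f"column {name!r} is constant")
    r, _ = stats.pearsonr(rows["score"], rows[column])
    return float(r), len(rows)


def _ols_r2(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """(R², BIC) of an OLS fit with intercept."""
    model = sm.OLS(y, sm.add_constant(x, has_constant="add"))
    fit = model.fit()
    return float(fit.rsquared), float(fit.bic)


def hierarchical_delta_r2(
    bench: BenchmarkTable,
    step1: str,
    step2: str = DISTANCE_COLUMN,
) -> tuple[float, float, float]:
    """Unique variance of ``step2`` over ``step1``: (R²₁, R²₂, ΔR²).

    Fits human scores on the step-1 predictor alone, then on both; nested
    OLS guarantees ΔR² ≥ 0 (clamped against round-off).
    """
    rows = _joint_rows(bench, [step1, step2])
    if len(rows) < 4:
        raise InsufficientDataError(
            f"hierarchical regression needs >= 4 jointly covered rows, "
            f"got {len(rows)}"
        )
    x1 = rows[step1].to_numpy(dtype=np.float64)
    x2 = rows[step2].to_numpy(dtype=np.float64)
    if step1 != step2:
        r = np.corrcoef(x1, x2)[0, 1]
        if np.isclose(abs(r), 1.0, atol=1e-12):
            raise InsufficientDataError(
                f"predictors {step1!r} and {step2!r} are perfectly collinear"
            )
    y = rows["score"].to_numpy()
    r2_1, _ = _ols_r2(y, x1[:, None])
    r2_2, _ = _ols_r2(y, np.column_stack([x1, x2]))
    delta = max(r2_2 - r2_1, 0.0)
    return r2_1, r2_2, delta


def best_subset(bench: BenchmarkTable, predictors: list[str]) -> list[SubsetFit]:
    """Fit all non-empty predictor subsets by OLS, ranked by BIC.

    Evaluated on the rows jointly covered by *all* candidate predictors so
    every subset competes on identical data.  Ties in BIC break towards
    fewer predictors, then lexicographically.
    """
    if not predictors:
        raise ValueError("need at least one candidate predictor")
    if len(predictors) > 12:
        raise ValueError("exhaustive search is limited to 12 predictors")
    rows = _joint_rows(bench, list(predictors))
    if len(rows) < len(predictors) + 2:
        raise InsufficientDataError(
            f"best-subset search needs more rows ({len(rows)}) than "
            f"predictors ({len(predictors)})"
        )
    y = rows["score"].to_numpy()
    fits = []
    for size in range(1, len(predictors) + 1):
        for subset in combinations(sorted(predictors), size):
            x = rows[list(subset)].to_numpy()
            r2, bic = _ols_r2(y, x)
            fits.append(SubsetFit(predictors=subset, r2=r2, bic=bic, n=len(rows)))
    fits.sort(key=lambda f: (f.bic, len(f.predictors), f.predictors))
    return fits


def concreteness_split(
    bench: BenchmarkTable, cmap: ConcretenessMap
) -> dict[str, BenchmarkTable]:
    """Partition pairs into abstract–abstract / mixed / concrete–concrete.

    A word is abstract if its concreteness rating is < threshold (scale
    midpoint 3 by default) and concrete if ≥ threshold.  Pairs with either
    word missing from the map land in an ``unsplit`` bucket.
    """
    groups: dict[str, list[int]] = {
        "abstract": [], "mixed": [], "concrete": [], "unsplit": []
    }
    for i, (w1, w2) in enumerate(zip(bench.frame["word1"], bench.frame["word2"])):
        c1, c2 = cmap.category(w1), cmap.category(w2)
        if c1 is None or c2 is None:
            groups["unsplit"].append(i)
        elif c1 == c2 == "abstract":
            groups["abstract"].append(i)
        elif c1 == c2 == "concrete":
            groups["concrete"].append(i)
        else:
            groups["mixed"].append(i)
    return {
        name: BenchmarkTable(
            name=f"{bench.name}:{name}",
            frame=bench.frame.iloc[idx].reset_index(drop=True),
        )
        for name, idx in groups.items()
    }


def evaluate(
    bench: BenchmarkTable,
    table: NormsTable,
    spec: MetricSpec | None = None,
    predictors_path: str | Path | None = None,
    concreteness: ConcretenessMap | None = None,
) -> EvalReport:
    """Run the full evaluation pipeline for one benchmark."""
    spec = spec or MetricSpec()
    if predictors_path is not None:
        bench = attach_predictors(bench, predictors_path)
    bench, covered = attach_distance(bench, table, spec)

    coverage = {DISTANCE_COLUMN: covered, "benchmark_size": bench.n_pairs}
    predictor_cols = [c for c in bench.predictor_columns]
    for col in predictor_cols:
        coverage[col] = int(bench.frame[col].notna().sum())
    joint = bench.frame[predictor_cols].dropna()
    coverage["joint"] = len(joint)

    correlations = {}
    for col in predictor_cols:
        try:
            correlations[col] = correlate(bench, col)
        except (InsufficientDataError, UndefinedCorrelationError):
            continue

    delta_entries = []
    alternatives = [c for c in predictor_cols if c != DISTANCE_COLUMN]
    for col in alternatives:
        try:
            r2_1, r2_2, delta = hierarchical_delta_r2(bench, step1=col)
        except InsufficientDataError:
            continue
        delta_entries.append({
            "step1_predictor": col,
            "r2_step1": r2_1,
            "r2_step2_with_sensorimotor": r2_2,
            "delta": delta,
        })

    try:
        subsets = best_subset(bench, predictor_cols)
    except InsufficientDataError:
        subsets = []

    splits = split_sizes = None
    if concreteness is not None:
        parts = concreteness_split(bench, concreteness)
        split_sizes = {k: v.n_pairs for k, v in parts.items()}
        splits = {}
        for name in ("abstract", "mixed", "concrete"):
            try:
                splits[name] = correlate(parts[name], DISTANCE_COLUMN)
            except (InsufficientDataError, UndefinedCorrelationError):
                continue

    return EvalReport(
        benchmark=bench.name,
        metric=spec.kind,
        coverage=coverage,
        correlations=correlations,
        delta_r2=delta_entries,
        best_subset=subsets,
        splits=splits,
        split_sizes=split_sizes,
    )
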