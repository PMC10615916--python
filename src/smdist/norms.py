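"""Loading, validating and keying sensorimotor norms tables.

A norms table holds one row per concept word with mean ratings on 11
sensorimotor dimensions — six perceptual modalities (auditory, gustatory,
haptic, interoceptive, olfactory, visual) and five action effectors
(foot/leg, hand/arm, head, mouth/throat, torso) — each on a 0–5 scale.
The Lancaster Sensorimotor Norms distribute exactly this layout as CSV and
are the intended full-scale input (39,707 concepts); any delimited file
with the same information loads through a :class:`ColumnMap`.

Word keys are normalised (case-folded, whitespace collapsed) so that the
upper-case labels used by published norms and the lower-case words used by
similarity benchmarks join on the same key.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DuplicateWordError,
    InvalidWordError,
    SchemaError,
    ValidationError,
    WordNotFoundError,
)

#: Canonical dimension order, fixed across the whole package.  The first six
#: are perceptual modalities, the last five action effectors.  This is also
#: the clockwise-from-top order used for polar-plot profiles.
DIMENSIONS: tuple[str, ...] = (
    "auditory",
    "gustatory",
    "haptic",
    "interoceptive",
    "olfactory",
    "visual",
    "foot_leg",
    "hand_arm",
    "head",
    "mouth_throat",
    "torso",
)

N_DIMENSIONS = len(DIMENSIONS)

RATING_MIN = 0.0
RATING_MAX = 5.0

_WS_RUN = re.compile(r"\s+")


def normalize_word(label: str) -> str:
    """Return the canonical key for a word label.

    Case-folded, leading/trailing whitespace stripped, internal whitespace
    runs collapsed to single spaces.  Deterministic and idempotent.

    Raises
    ------
    InvalidWordError
        If the label is empty after trimming.
    """
    key = _WS_RUN.sub(" ", str(label).strip()).casefold()
    if not key:
        raise InvalidWordError(f"empty word label: {label!r}")
    return key


@dataclass(frozen=True)
class SensorimotorVector:
    """One concept's 11 mean sensorimotor ratings, in canonical order."""

    word: str
    ratings: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ratings) != N_DIMENSIONS:
            raise ValidationError(
                f"{self.word!r}: expected {N_DIMENSIONS} ratings, "
                f"got {len(self.ratings)}"
            )
        for dim, value in zip(DIMENSIONS, self.ratings):
            if not np.isfinite(value) or not (RATING_MIN <= value <= RATING_MAX):
                raise ValidationError(
                    f"{self.word!r}: rating {value!r} for dimension {dim!r} "
                    f"outside [{RATING_MIN:g}, {RATING_MAX:g}]"
                )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.ratings, dtype=np.float64)

    def __getitem__(self, dimension: str) -> float:
        return self.ratings[DIMENSIONS.index(dimension)]


@dataclass(frozen=True)
class ColumnMap:
    """Maps file columns onto the word label and the 11 canonical dimensions.

    ``rating_columns`` pairs one file column name with each entry of
    :data:`DIMENSIONS`, in order.
    """

    word_column: str
    rating_columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rating_columns) != N_DIMENSIONS:
            raise SchemaError(
                f"column map needs {N_DIMENSIONS} rating columns, "
                f"got {len(self.rating_columns)}"
            )
        if len(set(self.rating_columns)) != N_DIMENSIONS:
            raise SchemaError("rating column names must be distinct")

    @classmethod
    def lancaster(cls) -> "ColumnMap":
        """Default map for the published Lancaster Sensorimotor Norms header."""
        return cls(
            word_column="Word",
            rating_columns=(
                "Auditory.mean",
                "Gustatory.mean",
                "Haptic.mean",
                "Interoceptive.mean",
                "Olfactory.mean",
                "Visual.mean",
                "Foot_leg.mean",
                "Hand_arm.mean",
                "Head.mean",
                "Mouth.mean",
                "Torso.mean",
            ),
        )


class NormsTable:
    """Keyed, validated collection of sensorimotor vectors.

    Entries are stored sorted by normalised key, so two files containing the
    same rows in any order produce identical tables (and identical matrix
    row order everywhere downstream).
    """

    def __init__(
        self, vectors: Iterable[SensorimotorVector], source: str = "<memory>"
    ):
        entries: dict[str, SensorimotorVector] = {}
        for vec in vectors:
            key = normalize_word(vec.word)
            if key in entries:
                raise DuplicateWordError(
                    f"duplicate word key {key!r} "
                    f"(labels {entries[key].word!r} and {vec.word!r})"
                )
            entries[key] = vec
        self._entries: dict[str, SensorimotorVector] = dict(sorted(entries.items()))
        self.source = source
        self._matrix: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self._entries)

    def __len__(self) -> int:
        return self.n

    def __contains__(self, word: str) -> bool:
        try:
            return normalize_word(word) in self._entries
        except InvalidWordError:
            return False

    def __iter__(self) -> Iterator[SensorimotorVector]:
        return iter(self._entries.values())

    @property
    def words(self) -> tuple[str, ...]:
        """Normalised keys in table (sorted) order."""
        return tuple(self._entries)

    @property
    def entries(self) -> Mapping[str, SensorimotorVector]:
        return dict(self._entries)

    @property
    def matrix(self) -> np.ndarray:
        """(n, 11) float64 rating matrix, rows aligned with :attr:`words`."""
        if self._matrix is None:
            self._matrix = np.array(
                [v.ratings for v in self._entries.values()], dtype=np.float64
            )
            self._matrix.setflags(write=False)
        return self._matrix

    def get_vector(self, word: str) -> SensorimotorVector:
        key = normalize_word(word)
        try:
            return self._entries[key]
        except KeyError:
            raise WordNotFoundError(key) from None

    def index_of(self, word: str) -> int:
        key = normalize_word(word)
        words = self.words
        try:
            # words is sorted, but a dict lookup is clearer than bisect here
            return words.index(key)
        except ValueError:
            raise WordNotFoundError(key) from None

    def __repr__(self) -> str:
        return f"NormsTable(n={self.n}, source={self.source!r})"


def get_vector(table: NormsTable, word: str) -> SensorimotorVector:
    """Look up a word's vector via the normalised key (function form of
    :meth:`NormsTable.get_vector`)."""
    return table.get_vector(word)


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")


def load_norms(path: str | Path, column_map: ColumnMap | None = None) -> NormsTable:
    """Read a delimited norms file into a validated :class:`NormsTable`.

    Parameters
    ----------
    path
        CSV or TSV file (delimiter chosen by extension) with a header row.
    column_map
        Mapping from file columns to the canonical dimensions; defaults to
        the published Lancaster norms header.

    Raises
    ------
    SchemaError
        A mapped column is missing from the header.
    ValidationError
        A rating is non-numeric or outside [0, 5]; the message names the
        row (1-based data row) and the column.
    DuplicateWordError
        Two rows normalise to the same key.
    """
    path = Path(path)
    cmap = column_map or ColumnMap.lancaster()
    frame = _read_delimited(path)

    missing = [
        c for c in (cmap.word_column, *cmap.rating_columns) if c not in frame.columns
    ]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing!r}")

    vectors: list[SensorimotorVector] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        record = dict(zip(frame.columns, row))
        label = record[cmap.word_column]
        ratings = []
        for dim, col in zip(DIMENSIONS, cmap.rating_columns):
            raw = record[col]
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: row {row_number}, column {col!r}: "
                    f"non-numeric rating {raw!r}"
                ) from None
            if not np.isfinite(value) or not (RATING_MIN <= value <= RATING_MAX):
                raise ValidationError(
                    f"{path}: row {row_number}, column {col!r}: rating {value!r} "
                    f"outside [{RATING_MIN:g}, {RATING_MAX:g}]"
                )
            ratings.append(value)
        vectors.append(SensorimotorVector(word=str(label), ratings=tuple(ratings)))

    return NormsTable(vectors, source=str(path))


def write_norms(table: NormsTable, path: str | Path,
                column_map: ColumnMap | None = None) -> Path:
    """Write a table back to delimited text in the given (default Lancaster)
    header layout, so generated fixtures round-trip through :func:`load_norms`."""
    path = Path(path)
    cmap = column_map or ColumnMap.lancaster()
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.DataFrame(
        [(v.word, *v.ratings) for v in table],
        columns=[cmap.word_column, *cmap.rating_columns],
    )
    frame.to_csv(path, sep=sep, index=False, lineterminator="\n")
    return path
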