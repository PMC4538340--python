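"""Core data model: items, score tables, ranked lists and ensembles.

A :class:`RankedList` is a named total order over string item ids with
1-based ranks (rank 1 = best).  Score-to-rank conversion is deterministic:
ties are broken by ascending item id, never by average ranks, because the
footrule machinery downstream requires total orders.

Docking energies and EC50-style potencies both default to
``lower_is_better`` (a more negative binding energy and a more potent
compound both rank first).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Direction",
    "RankedList",
    "ScoreTable",
    "RankEnsemble",
    "scores_to_rank",
    "restrict",
    "read_ranked_list_tsv",
    "write_ranked_list_tsv",
    "read_score_table",
]


class Direction(str, enum.Enum):
    """Orientation of a score column: which end of the scale is best."""

    LOWER = "lower_is_better"
    HIGHER = "higher_is_better"

    @classmethod
    def coerce(cls, value: "Direction | str") -> "Direction":
        if isinstance(value, Direction):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ValueError(
                f"unknown direction {value!r}; expected "
                f"'lower_is_better' or 'higher_is_better'"
            ) from None


class IngestError(ValueError):
    """Raised when an input table or score map violates the data contract."""


def _clean_id(raw: str) -> str:
    item = str(raw).strip()
    if not item:
        raise IngestError("empty item id after whitespace trimming")
    return item


@dataclass(frozen=True)
class RankedList:
    """A named total ordering of item ids, optionally carrying scores.

    Parameters
    ----------
    name:
        Label for the list, e.g. a scoring-function name or ``"EC50"``.
    items:
        Item ids ordered best-first; position ``i`` (0-based) has rank
        ``i + 1``.
    scores:
        Optional map id -> score, oriented so that the rank-1 item carries
        the best score (same direction convention as the ordering).
    """

    name: str
    items: tuple[str, ...]
    scores: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        cleaned = tuple(_clean_id(t) for t in self.items)
        object.__setattr__(self, "items", cleaned)
        if len(set(cleaned)) != len(cleaned):
            seen: set[str] = set()
            dups = sorted({t for t in cleaned if t in seen or seen.add(t)})
            raise IngestError(f"duplicate items in list {self.name!r}: {dups}")
        if not cleaned:
            raise IngestError(f"ranked list {self.name!r} is empty")
        if self.scores is not None:
            missing = [t for t in cleaned if t not in self.scores]
            if missing:
                raise IngestError(
                    f"list {self.name!r}: scores missing for {missing}"
                )
        object.__setattr__(
            self, "_rank", {t: i + 1 for i, t in enumerate(cleaned)}
        )

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, item: str) -> bool:
        return item in self._rank  # type: ignore[attr-defined]

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.items)

    def rank(self, item: str) -> int:
        """1-based rank of *item*; raises ``KeyError`` if absent."""
        return self._rank[item]  # type: ignore[attr-defined]

    @property
    def ranks(self) -> Mapping[str, int]:
        return dict(self._rank)  # type: ignore[attr-defined]

    def top(self, k: int) -> tuple[str, ...]:
        return self.items[:k]


def scores_to_rank(
    scores: Mapping[str, float],
    direction: Direction | str = Direction.LOWER,
    name: str = "scores",
) -> RankedList:
    """Convert a score map into a full ranking.

    The best score receives rank 1; ties are broken by ascending item id so
    the result is a deterministic total order.

    Raises
    ------
    IngestError
        If the map is empty or any score is non-finite (the offending item
        is named in the message).
    """
    direction = Direction.coerce(direction)
    if not scores:
        raise IngestError(f"cannot rank {name!r}: empty score map")
    cleaned: dict[str, float] = {}
    for raw, s in scores.items():
        item = _clean_id(raw)
        s = float(s)
        if not math.isfinite(s):
            raise IngestError(f"non-finite score for item {item!r} in {name!r}")
        if item in cleaned:
            raise IngestError(f"duplicate item id {item!r} in {name!r}")
        cleaned[item] = s
    sign = 1.0 if direction is Direction.LOWER else -1.0
    order = sorted(cleaned, key=lambda t: (sign * cleaned[t], t))
    return RankedList(name=name, items=tuple(order), scores=cleaned)


def restrict(ranked: RankedList, universe: Iterable[str]) -> RankedList:
    """Restrict *ranked* to *universe*, recompacting ranks to ``1..|universe|``.

    Relative order is preserved.  Every requested id must be present.
    """
    keep = {_clean_id(t) for t in universe}
    missing = sorted(keep - ranked.universe)
    if missing:
        raise IngestError(
            f"cannot restrict {ranked.name!r}: ids not in list: {missing}"
        )
    items = tuple(t for t in ranked.items if t in keep)
    scores = (
        {t: ranked.scores[t] for t in items} if ranked.scores is not None else None
    )
    return RankedList(name=ranked.name, items=items, scores=scores)


@dataclass(frozen=True)
class ScoreTable:
    """Items x scorers real matrix with a per-scorer direction.

    The canonical container is a pandas DataFrame (index = item ids,
    columns = scorer names).  Missing values are rejected on construction;
    partial (top-k) inputs must be expressed as explicit top-k ranked
    lists instead.
    """

    values: pd.DataFrame
    directions: Mapping[str, Direction]

    def __post_init__(self) -> None:
        df = self.values.copy()
        df.index = [_clean_id(t) for t in df.index]
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise IngestError(f"duplicate item ids in score table: {dups}")
        if len(set(df.columns)) != len(df.columns):
            raise IngestError("scorer names must be unique")
        if df.empty:
            raise IngestError("score table is empty")
        bad = df.columns[~np.isfinite(df.to_numpy(dtype=float)).all(axis=0)]
        if len(bad):
            raise IngestError(
                f"score table has missing/non-finite values in columns: "
                f"{sorted(bad)}"
            )
        dirs = {c: Direction.coerce(self.directions.get(c, Direction.LOWER))
                for c in df.columns}
        object.__setattr__(self, "values", df.astype(float))
        object.__setattr__(self, "directions", dirs)

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def scorers(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def column(self, scorer: str) -> Mapping[str, float]:
        return self.values[scorer].to_dict()

    def ranked_list(self, scorer: str) -> RankedList:
        return scores_to_rank(
            self.column(scorer), self.directions[scorer], name=scorer
        )

    def ranked_lists(self) -> list[RankedList]:
        return [self.ranked_list(c) for c in self.scorers]

    def to_csv(self, path: str | Path | None = None, sep: str = ",") -> str | None:
        out = self.values.copy()
        out.insert(0, "item", out.index)
        text = out.to_csv(index=False, sep=sep, lineterminator="\n")
        if path is None:
            return text
        Path(path).write_text(text)
        return None


@dataclass(frozen=True)
class RankEnsemble:
    """A weighted collection of ranked lists over a common universe.

    ``strict=True`` (the default) requires every list to be a permutation
    of the identical universe; top-k inputs require ``strict=False`` and a
    missing-rank policy in the distance configuration.
    """

    lists: tuple[RankedList, ...]
    weights: Mapping[str, float] = field(default_factory=dict)
    strict: bool = True

    def __post_init__(self) -> None:
        lists = tuple(self.lists)
        if not lists:
            raise IngestError("ensemble needs at least one ranked list")
        names = [L.name for L in lists]
        if len(set(names)) != len(names):
            raise IngestError(f"duplicate list names in ensemble: {names}")
        w = {L.name: float(self.weights.get(L.name, 1.0)) for L in lists}
        if any(v <= 0 for v in w.values()):
            bad = sorted(k for k, v in w.items() if v <= 0)
            raise IngestError(f"ensemble weights must be > 0; bad: {bad}")
        if self.strict:
            ref = lists[0].universe
            for L in lists[1:]:
                if L.universe != ref:
                    diff = sorted(ref ^ L.universe)
                    raise IngestError(
                        f"list {L.name!r} is not over the common universe; "
                        f"symmetric difference: {diff}"
                    )
        object.__setattr__(self, "lists", lists)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.lists)

    @property
    def universe(self) -> frozenset[str]:
        u: frozenset[str] = frozenset()
        for L in self.lists:
            u |= L.universe
        return u

    def weight(self, name: str) -> float:
        return self.weights[name]


# ---------------------------------------------------------------------------
# plain-text I/O (TSV with header, LF endings, '.' decimal, no index column)
# ---------------------------------------------------------------------------

def read_ranked_list_tsv(path: str | Path, name: str | None = None) -> RankedList:
    """Read a two-column ``item<TAB>rank`` TSV (header required)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    cols = [c.strip().lower() for c in df.columns]
    if "item" not in cols or "rank" not in cols:
        raise IngestError(
            f"{path}: expected header with 'item' and 'rank' columns, "
            f"got {list(df.columns)}"
        )
    df.columns = cols
    df = df.sort_values("rank", kind="mergesort")
    ranks = df["rank"].to_numpy()
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(ranks, expected):
        raise IngestError(
            f"{path}: ranks must be a permutation of 1..{len(df)}"
        )
    return RankedList(name=name or path.stem, items=tuple(df["item"].astype(str)))


def write_ranked_list_tsv(ranked: RankedList, path: str | Path) -> None:
    lines = ["item\trank"]
    lines += [f"{t}\t{i + 1}" for i, t in enumerate(ranked.items)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_score_table(
    path: str | Path,
    directions: Mapping[str, Direction | str] | None = None,
    default_direction: Direction | str = Direction.LOWER,
    sep: str | None = None,
) -> ScoreTable:
    """Read a score table CSV/TSV; first column must be ``item``.

    Per-scorer directions come from *directions* (e.g. parsed from a
    sidecar YAML/JSON config); unlisted scorers use *default_direction*
    (docking energies are lower-is-better).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    first = df.columns[0]
    if first.strip().lower() != "item":
        raise IngestError(f"{path}: first column must be 'item', got {first!r}")
    df = df.set_index(first)
    default = Direction.coerce(default_direction)
    dirs = {c: default for c in df.columns}
    for key, val in (directions or {}).items():
        if key not in dirs:
            raise IngestError(f"{path}: direction given for unknown scorer {key!r}")
        dirs[key] = Direction.coerce(val)
    return ScoreTable(values=df, directions=dirs)
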