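"""Benchmark-replication harness for supplementary-table-shaped inputs.

The published consensus-screening study distributes two rank tables: one
with per-scoring-function ranks (and the potency-reference rank) for 107
compounds, and one with the final consensus rank plus reported-interaction
flags for 305 herbal ingredients.  The exact column layout of those files
is not standardized, so the harness takes a declared column mapping rather
than guessing, recomputes every quantity from the table values, and
reports relevance-convention sensitivity instead of asserting agreement
with any printed number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .aggregate import CEParams
from .distances import ConfigurationError, DistanceConfig
from .evaluate import (
    ReferenceRank,
    RelevanceScheme,
    detection_curve,
    detection_rate,
    relevance_from_reference,
    mean_ndcg,
    subset_sweep,
)
from .rank_core import IngestError, RankedList, ScoreTable

__all__ = ["Table1Report", "replicate_table1", "DetectionReport",
           "replicate_detection", "ranked_list_from_rank_column"]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip() for c in df.columns]
    return df


def ranked_list_from_rank_column(
    df: pd.DataFrame, item_col: str, rank_col: str, name: str | None = None
) -> RankedList:
    """Build a RankedList from an integer rank column (1..n permutation)."""
    sub = df[[item_col, rank_col]].copy()
    bad = sub[rank_col].isna() | sub[item_col].isna()
    if bad.any():
        rows = [int(i) + 2 for i in sub.index[bad]]  # +2: header + 1-basing
        raise IngestError(f"malformed rank table rows (1-based, incl. header): {rows}")
    sub = sub.sort_values(rank_col, kind="mergesort")
    ranks = sub[rank_col].to_numpy()
    if sorted(ranks) != list(range(1, len(sub) + 1)):
        raise IngestError(
            f"column {rank_col!r} is not a permutation of 1..{len(sub)}"
        )
    return RankedList(
        name=name or rank_col, items=tuple(sub[item_col].astype(str))
    )


@dataclass(frozen=True)
class Table1Report:
    """Mean nDCG per scorer subset under each relevance convention."""

    values: pd.DataFrame  # index: subset label; columns: conventions
    conventions: tuple[str, ...]
    closest_convention: str | None  # vs printed values, if provided
    deviations: Mapping[str, float] | None


def replicate_table1(
    path: str | Path,
    item_col: str = "item",
    reference_col: str = "EC50",
    scorer_cols: Sequence[str] | None = None,
    activity_col: str | None = None,
    binary_threshold: float | None = None,
    params: CEParams | None = None,
    cfg: DistanceConfig | None = None,
    printed: Mapping[str, float] | None = None,
) -> Table1Report:
    """Recompute the full scorer-subset mean-nDCG table from a rank file.

    The file must carry an item column, a reference rank column, and one
    rank column per scoring function.  Every non-empty scorer subset is
    evaluated (singletons directly, larger subsets via cross-entropy
    aggregation) under each relevance convention; ``binary`` joins the
    sweep only when an activity column and threshold are supplied.  If
    *printed* maps subset labels to published values, the report names the
    convention with the smallest mean absolute deviation — it never
    asserts a match.
    """
    df = _read_table(path)
    for col in [item_col, reference_col]:
        if col not in df.columns:
            raise IngestError(f"missing required column {col!r}")
    scorers = list(scorer_cols) if scorer_cols is not None else [
        c for c in df.columns
        if c not in {item_col, reference_col, activity_col}
    ]
    if len(scorers) < 2:
        raise IngestError("need at least two scorer rank columns")
    if params is None:
        raise ConfigurationError("CEParams with an explicit seed is required")
    cfg = cfg or DistanceConfig(metric="weighted_footrule")

    ref_list = ranked_list_from_rank_column(df, item_col, reference_col)
    if activity_col is not None:
        acts = dict(
            zip(df[item_col].astype(str), df[activity_col].astype(float))
        )
    else:
        # rank itself serves as the (lower-is-better) activity surrogate
        acts = {t: float(r) for t, r in ref_list.ranks.items()}
    ref = ReferenceRank(ranking=ref_list, activities=acts)

    # Express scorer ranks as a score table (rank value = score, lower best)
    values = pd.DataFrame(
        {
            s: ranked_list_from_rank_column(df, item_col, s).ranks
            for s in scorers
        }
    ).astype(float)
    table = ScoreTable(values=values, directions={})

    conventions: list[tuple[str, RelevanceScheme, float | None]] = [
        ("linear", RelevanceScheme.LINEAR, None),
        ("exponential", RelevanceScheme.EXPONENTIAL, None),
    ]
    if activity_col is not None and binary_threshold is not None:
        conventions.append(("binary", RelevanceScheme.BINARY, binary_threshold))

    columns: dict[str, dict[str, float]] = {}
    for label, scheme, threshold in conventions:
        sweep = subset_sweep(
            table, ref, cfg=cfg, params=params, scheme=scheme,
            threshold=threshold,
        )
        joiner = "" if all(len(s) == 1 for s in scorers) else "+"
        columns[label] = {joiner.join(r.scorers): r.mean_ndcg for r in sweep}
    # the reference against itself is 1 by construction; keep the row for
    # completeness of the table layout
    rel_cache = {
        label: relevance_from_reference(ref, scheme, threshold)
        for label, scheme, threshold in conventions
    }
    for label in columns:
        columns[label][reference_col] = mean_ndcg(ref_list, rel_cache[label])

    report = pd.DataFrame(columns)
    report = report.sort_values(report.columns[0], ascending=False)

    closest = None
    deviations = None
    if printed:
        deviations = {}
        for label in report.columns:
            diffs = [
                abs(report.at[sub, label] - val)
                for sub, val in printed.items()
                if sub in report.index
            ]
            if diffs:
                deviations[label] = sum(diffs) / len(diffs)
        if deviations:
            closest = min(deviations, key=deviations.get)
    return Table1Report(
        values=report,
        conventions=tuple(report.columns),
        closest_convention=closest,
        deviations=deviations,
    )


@dataclass(frozen=True)
class DetectionReport:
    rate: float
    cutoff: int
    n_items: int
    n_positives: int
    curve: tuple[tuple[float, float], ...]


def replicate_detection(
    path: str | Path,
    top_fraction: float = 0.1,
    item_col: str = "item",
    rank_col: str = "rank",
    flag_col: str = "positive",
    curve_fractions: Sequence[float] = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.75, 1.0),
) -> DetectionReport:
    """Detection rate at a cutoff fraction plus a rate-versus-depth curve
    from a ranked file with positive-label flags."""
    df = _read_table(path)
    for col in [item_col, rank_col, flag_col]:
        if col not in df.columns:
            raise IngestError(f"missing required column {col!r}")
    ranking = ranked_list_from_rank_column(df, item_col, rank_col)
    flags = df[flag_col].astype(str).str.strip().str.upper()
    positives = {
        str(t)
        for t, f in zip(df[item_col].astype(str), flags)
        if f in {"Y", "YES", "TRUE", "1"}
    }
    import math

    k = max(1, math.floor(top_fraction * len(ranking)))
    return DetectionReport(
        rate=detection_rate(ranking, positives, top_fraction),
        cutoff=k,
        n_items=len(ranking),
        n_positives=len(positives),
        curve=tuple(detection_curve(ranking, positives, curve_fractions)),
    )
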