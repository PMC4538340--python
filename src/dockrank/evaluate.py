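"""Ranking evaluation: graded-relevance nDCG and detection-rate enrichment.

Discounted cumulative gain at cutoff p for a candidate ordering is

    DCG_p = rel_1 + sum_{i=2..p} rel_i / log2(i),

with rel_i the graded relevance of the item the candidate places at
position i (position 1 is undiscounted, log base 2).  Normalizing by the
ideal ordering's DCG gives nDCG_p in [0, 1].  The headline scalar used to
compare a candidate against a reference activity ranking is the arithmetic
mean of nDCG_p over every cutoff p = 1..n; an ``at_p`` mode reports a
single cutoff instead.

Relevance conventions (the activity literature states none, so all three
are exposed):

* ``linear`` (default, parameter-free): rel(t) = n - r_ref(t) + 1;
* ``exponential``: rel(t) = 2^(1 - r_ref(t)) (top item 1, halving — the
  scaled form keeps values finite for long lists);
* ``binary``: rel(t) = 1 if activity(t) <= threshold else 0, mirroring an
  active/inactive potency split such as EC50 <= 10 uM.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .aggregate import AggregationResult, CEParams, aggregate_ce
from .distances import ConfigurationError, DistanceConfig, Metric
from .rank_core import Direction, RankedList, RankEnsemble, ScoreTable, scores_to_rank

__all__ = [
    "ReferenceRank",
    "RelevanceScheme",
    "relevance_from_reference",
    "dcg",
    "ndcg",
    "mean_ndcg",
    "evaluate_ranking",
    "EvaluationResult",
    "SubsetResult",
    "subset_sweep",
    "detection_rate",
    "detection_curve",
]


@dataclass(frozen=True)
class ReferenceRank:
    """A reference ranked list plus the activity values behind it.

    Ordering must be consistent with activity under lower-is-better
    (a more potent compound — smaller EC50 — ranks first); ties may be
    broken arbitrarily but monotonicity is enforced.
    """

    ranking: RankedList
    activities: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [t for t in self.ranking.items if t not in self.activities]
        if missing:
            raise ConfigurationError(
                f"reference activities missing for items: {missing}"
            )
        vals = [float(self.activities[t]) for t in self.ranking.items]
        if any(b < a for a, b in zip(vals, vals[1:]) if not math.isclose(a, b)):
            raise ConfigurationError(
                "reference ordering is inconsistent with activities "
                "(activities must be non-decreasing along ranks)"
            )

    @classmethod
    def from_activities(
        cls, activities: Mapping[str, float], name: str = "reference"
    ) -> "ReferenceRank":
        ranking = scores_to_rank(activities, Direction.LOWER, name=name)
        return cls(ranking=ranking, activities=dict(activities))

    def __len__(self) -> int:
        return len(self.ranking)


class RelevanceScheme(str, enum.Enum):
    LINEAR = "linear"
    EXPONENTIAL = "exponential"
    BINARY = "binary"


def relevance_from_reference(
    ref: ReferenceRank,
    scheme: RelevanceScheme | str = RelevanceScheme.LINEAR,
    threshold: float | None = None,
) -> dict[str, float]:
    """Graded relevance per item derived from the reference ranking."""
    scheme = RelevanceScheme(scheme)
    n = len(ref)
    if scheme is RelevanceScheme.LINEAR:
        return {t: float(n - ref.ranking.rank(t) + 1) for t in ref.ranking.items}
    if scheme is RelevanceScheme.EXPONENTIAL:
        return {t: 2.0 ** (1 - ref.ranking.rank(t)) for t in ref.ranking.items}
    if threshold is None:
        raise ConfigurationError("binary relevance requires an activity threshold")
    return {
        t: 1.0 if float(ref.activities[t]) <= threshold else 0.0
        for t in ref.ranking.items
    }


def dcg(rel_sequence: Sequence[float], p: int) -> float:
    """DCG at cutoff *p* of relevances listed in candidate order."""
    n = len(rel_sequence)
    if not (1 <= p <= n):
        raise ValueError(f"cutoff p = {p} out of range 1..{n}")
    total = float(rel_sequence[0])
    for i in range(2, p + 1):
        total += float(rel_sequence[i - 1]) / math.log2(i)
    return total


def _rel_in_order(candidate: RankedList, rel: Mapping[str, float]) -> list[float]:
    missing = [t for t in candidate.items if t not in rel]
    if missing:
        raise ConfigurationError(f"relevance undefined for items: {missing}")
    values = [float(rel[t]) for t in candidate.items]
    if any(v < 0 for v in values):
        raise ConfigurationError("relevances must be >= 0")
    if not any(v > 0 for v in values):
        raise ConfigurationError(
            "all-zero relevance: nDCG is undefined (IDCG would be 0)"
        )
    return values


def ndcg(candidate: RankedList, rel: Mapping[str, float], p: int) -> float:
    """nDCG_p = DCG_p / IDCG_p, the ideal being relevance-descending order."""
    values = _rel_in_order(candidate, rel)
    ideal = sorted(values, reverse=True)
    return dcg(values, p) / dcg(ideal, p)


@dataclass(frozen=True)
class EvaluationResult:
    """Per-cutoff DCG/IDCG/nDCG plus the headline mean-over-cutoffs scalar."""

    candidate_name: str
    dcg_p: tuple[float, ...]
    idcg_p: tuple[float, ...]
    ndcg_p: tuple[float, ...]
    mean_ndcg: float
    scheme: str


def evaluate_ranking(
    candidate: RankedList,
    rel: Mapping[str, float],
    scheme: str = "linear",
) -> EvaluationResult:
    values = _rel_in_order(candidate, rel)
    ideal = sorted(values, reverse=True)
    n = len(values)
    discounts = np.ones(n)
    if n > 1:
        discounts[1:] = 1.0 / np.log2(np.arange(2, n + 1))
    dcg_p = np.cumsum(np.asarray(values) * discounts)
    idcg_p = np.cumsum(np.asarray(ideal) * discounts)
    ndcg_p = dcg_p / idcg_p
    return EvaluationResult(
        candidate_name=candidate.name,
        dcg_p=tuple(dcg_p),
        idcg_p=tuple(idcg_p),
        ndcg_p=tuple(ndcg_p),
        mean_ndcg=float(ndcg_p.mean()),
        scheme=scheme,
    )


def mean_ndcg(candidate: RankedList, rel: Mapping[str, float]) -> float:
    """Arithmetic mean of nDCG_p over all cutoffs p = 1..n."""
    return evaluate_ranking(candidate, rel).mean_ndcg


# ---------------------------------------------------------------------------
# scorer-subset sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubsetResult:
    scorers: tuple[str, ...]
    mean_ndcg: float
    objective: float | None  # Phi of the consensus; None for singletons
    seed: int | None


def _enumerate_subsets(scorers: Sequence[str]) -> list[tuple[str, ...]]:
    out: list[tuple[str, ...]] = []
    for size in range(1, len(scorers) + 1):
        out.extend(itertools.combinations(scorers, size))
    return out


def subset_sweep(
    table: ScoreTable,
    ref: ReferenceRank,
    cfg: DistanceConfig | None = None,
    params: CEParams | None = None,
    scheme: RelevanceScheme | str = RelevanceScheme.LINEAR,
    threshold: float | None = None,
    subsets: Iterable[Sequence[str]] | None = None,
) -> list[SubsetResult]:
    """Mean nDCG versus the reference for every non-empty scorer subset.

    Singletons are evaluated directly from the score column; larger
    subsets are first fused with :func:`aggregate_ce` (each subset gets a
    sub-seed derived deterministically from ``params.seed`` and its index
    in the enumeration, so the whole sweep is reproducible).  Results are
    returned sorted by mean nDCG, best first.

    Unless a distance configuration is supplied, aggregation minimizes the
    weighted footrule with linear-rank importance — the top-weighted
    distance the consensus-docking method defines, whose optimum is the
    mean-rank ordering.

    An exhaustive sweep over more than 12 scorers is refused (2^k
    blow-up); pass an explicit ``subsets`` list instead.
    """
    cfg = cfg or DistanceConfig(metric=Metric.WEIGHTED_FOOTRULE)
    scorers = table.scorers
    if len(scorers) < 2:
        raise ConfigurationError("subset sweep needs at least 2 scorers")
    if subsets is None:
        if len(scorers) > 12:
            raise ConfigurationError(
                f"refusing exhaustive sweep over {len(scorers)} scorers "
                f"(2^k subsets); pass an explicit subset list"
            )
        todo = _enumerate_subsets(scorers)
    else:
        todo = [tuple(s) for s in subsets]
        for sub in todo:
            unknown = [s for s in sub if s not in scorers]
            if unknown:
                raise ConfigurationError(f"unknown scorers in subset: {unknown}")
            if not sub:
                raise ConfigurationError("empty scorer subset")
    if params is None:
        raise ConfigurationError("CEParams with an explicit seed is required")

    rel = relevance_from_reference(ref, scheme, threshold)
    lists = {s: table.ranked_list(s) for s in scorers}
    results: list[SubsetResult] = []
    for idx, sub in enumerate(todo):
        if len(sub) == 1:
            candidate = lists[sub[0]]
            phi = None
            seed = None
        else:
            seed = int(params.seed + 1000 * (idx + 1)) % (2**31 - 1)
            sub_params = replace(params, seed=seed)
            agg = aggregate_ce(
                RankEnsemble(lists=tuple(lists[s] for s in sub)),
                cfg,
                sub_params,
            )
            candidate = agg.best_list
            phi = agg.objective
        results.append(
            SubsetResult(
                scorers=sub,
                mean_ndcg=mean_ndcg(candidate, rel),
                objective=phi,
                seed=seed,
            )
        )
    results.sort(key=lambda r: (-r.mean_ndcg, len(r.scorers), r.scorers))
    return results


# ---------------------------------------------------------------------------
# detection rate (enrichment against a positive-label set)
# ---------------------------------------------------------------------------

def detection_rate(
    ranking: RankedList, positives: Iterable[str], top_fraction: float = 0.1
) -> float:
    """Fraction of the top slice of the ranking that carries a positive label.

    The cutoff is ``max(1, floor(top_fraction * n))``: the top 10 percent
    of a 305-item list is 30 items, and a fraction too small to cover one
    item still evaluates the single top item.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    pos = {str(t).strip() for t in positives}
    unknown = sorted(pos - ranking.universe)
    if unknown:
        raise ConfigurationError(
            f"positive ids not in the ranking universe: {unknown}"
        )
    k = max(1, math.floor(top_fraction * len(ranking)))
    top = ranking.top(k)
    return sum(1 for t in top if t in pos) / k


def detection_curve(
    ranking: RankedList,
    positives: Iterable[str],
    fractions: Sequence[float] = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.75, 1.0),
) -> list[tuple[float, float]]:
    """Detection rate at several cutoff fractions, for rate-vs-depth curves."""
    pos = set(positives)
    return [(f, detection_rate(ranking, pos, f)) for f in fractions]
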