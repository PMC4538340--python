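"""Rank distances and the aggregation objective.

Spearman's footrule between two rankings is the sum of absolute rank
differences over the union of their items,

    S(L1, L2) = sum_t | r_L1(t) - r_L2(t) |.

The weighted variant scales each item's term by the difference of an
importance function M of the two ranks,

    WS(L1, L2) = sum_t | M(r_L1(t)) - M(r_L2(t)) | * | r_L1(t) - r_L2(t) |,

so disagreements near the top of the lists (where M changes fastest under
a top-weighted M) cost more.  The aggregation objective for an ensemble
{(L_i, w_i)} is

    Phi(delta) = sum_i w_i * d(delta, L_i),

minimized over candidate permutations delta by the aggregator module.

M is configurable because the literature offers more than one convention:

* ``linear_rank``: M(r) = (n - r + 1) / n, a parameter-free rank-importance
  weight decreasing linearly from 1 at the top to 1/n at the bottom;
* ``normalized_score``: M is the min-max normalized raw score of the item
  in its own list (1 = best-scoring item), requiring both lists to carry
  scores.

Partial (top-k) lists: an item absent from a list is assigned rank k+1 in
that list — the standard top-k footrule convention — when the policy is
``assign_k_plus_1``; ``strict`` (the default) rejects universe mismatches.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .rank_core import RankedList, RankEnsemble

__all__ = [
    "Metric",
    "WeightFunction",
    "MissingRankPolicy",
    "DistanceConfig",
    "ConfigurationError",
    "spearman_footrule",
    "weighted_footrule",
    "rank_distance",
    "objective_phi",
]


class Metric(str, enum.Enum):
    FOOTRULE = "footrule"
    WEIGHTED_FOOTRULE = "weighted_footrule"


class WeightFunction(str, enum.Enum):
    LINEAR_RANK = "linear_rank"
    NORMALIZED_SCORE = "normalized_score"


class MissingRankPolicy(str, enum.Enum):
    STRICT = "strict"
    ASSIGN_K_PLUS_1 = "assign_k_plus_1"


class ConfigurationError(ValueError):
    """Raised for invalid or inconsistent distance configurations."""


@dataclass(frozen=True)
class DistanceConfig:
    metric: Metric = Metric.FOOTRULE
    weight_function: WeightFunction = WeightFunction.LINEAR_RANK
    missing_rank_policy: MissingRankPolicy = MissingRankPolicy.STRICT

    def __post_init__(self) -> None:
        object.__setattr__(self, "metric", Metric(self.metric))
        object.__setattr__(
            self, "weight_function", WeightFunction(self.weight_function)
        )
        object.__setattr__(
            self, "missing_rank_policy", MissingRankPolicy(self.missing_rank_policy)
        )


def _union_ranks(
    L1: RankedList, L2: RankedList, cfg: DistanceConfig
) -> list[tuple[str, int, int]]:
    """(item, r1, r2) over the union, applying the missing-rank policy."""
    union = L1.universe | L2.universe
    if L1.universe != L2.universe:
        if cfg.missing_rank_policy is MissingRankPolicy.STRICT:
            diff = sorted(L1.universe ^ L2.universe)
            raise ConfigurationError(
                f"lists {L1.name!r} and {L2.name!r} are not over the same "
                f"universe (strict mode); symmetric difference: {diff}"
            )
    k1, k2 = len(L1), len(L2)
    out = []
    for t in sorted(union):
        r1 = L1.rank(t) if t in L1 else k1 + 1
        r2 = L2.rank(t) if t in L2 else k2 + 1
        out.append((t, r1, r2))
    return out


def spearman_footrule(
    L1: RankedList, L2: RankedList, cfg: DistanceConfig | None = None
) -> float:
    """Unweighted Spearman footrule distance (sum of |rank differences|)."""
    cfg = cfg or DistanceConfig()
    return float(sum(abs(r1 - r2) for _, r1, r2 in _union_ranks(L1, L2, cfg)))


def _importance(L: RankedList, cfg: DistanceConfig) -> dict[str, float]:
    """Per-item importance M(r_L(t)); items not in L get M = 0 (bottom)."""
    n = len(L)
    if cfg.weight_function is WeightFunction.LINEAR_RANK:
        return {t: (n - L.rank(t) + 1) / n for t in L.items}
    if L.scores is None:
        raise ConfigurationError(
            f"weight function 'normalized_score' requires list {L.name!r} "
            f"to carry scores"
        )
    best = L.scores[L.items[0]]
    worst = L.scores[L.items[-1]]
    if best == worst:  # constant scores: every item equally important
        return {t: 1.0 for t in L.items}
    return {t: (L.scores[t] - worst) / (best - worst) for t in L.items}


def weighted_footrule(
    L1: RankedList, L2: RankedList, cfg: DistanceConfig | None = None
) -> float:
    """Weighted Spearman footrule distance under the configured M."""
    cfg = cfg or DistanceConfig(metric=Metric.WEIGHTED_FOOTRULE)
    m1 = _importance(L1, cfg)
    m2 = _importance(L2, cfg)
    total = 0.0
    for t, r1, r2 in _union_ranks(L1, L2, cfg):
        total += abs(m1.get(t, 0.0) - m2.get(t, 0.0)) * abs(r1 - r2)
    return total


def rank_distance(
    L1: RankedList, L2: RankedList, cfg: DistanceConfig | None = None
) -> float:
    """Dispatch on ``cfg.metric``."""
    cfg = cfg or DistanceConfig()
    if cfg.metric is Metric.FOOTRULE:
        return spearman_footrule(L1, L2, cfg)
    return weighted_footrule(L1, L2, cfg)


def objective_phi(
    candidate: RankedList,
    ensemble: RankEnsemble,
    cfg: DistanceConfig | None = None,
) -> float:
    """Aggregation objective Phi(delta) = sum_i w_i d(delta, L_i).

    Linear in the ensemble weights.  In strict mode the candidate must be
    a permutation of the ensemble universe.
    """
    cfg = cfg or DistanceConfig()
    if (
        cfg.missing_rank_policy is MissingRankPolicy.STRICT
        and candidate.universe != ensemble.universe
    ):
        diff = sorted(candidate.universe ^ ensemble.universe)
        raise ConfigurationError(
            f"candidate universe differs from ensemble universe: {diff}"
        )
    return sum(
        ensemble.weight(L.name) * rank_distance(candidate, L, cfg)
        for L in ensemble.lists
    )
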