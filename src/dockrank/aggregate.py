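"""Consensus ranking: minimize Phi over permutations.

Two solvers share a fast integer-array representation of the objective:

* :func:`aggregate_ce` — cross-entropy Monte Carlo search.  It maintains an
  n x n item-by-position probability matrix P (uniform at the start), each
  iteration samples permutations position-by-position from P (renormalized
  over unused items), scores them, refits P to the elite fraction with
  exponential smoothing, and stops on an iteration cap or when the incumbent
  best objective stagnates.  The consensus is the best permutation ever
  *sampled* (the incumbent, not a mode of P, which guards against
  smoothing-induced drift), finished with a deterministic pairwise-swap
  descent — the usual memetic refinement for permutation samplers, without
  which the raw sampler is far from the optimum at the hundred-item scale.
* :func:`aggregate_brute_force` — exact enumeration over all n! candidates,
  guarded to n <= 8; it is the testing oracle for the stochastic search.

Only full permutations of a common universe are aggregated here; top-k
inputs must be completed or restricted first.  The ``normalized_score``
weight function is rejected because a sampled candidate carries no raw
scores to normalize.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .distances import (
    ConfigurationError,
    DistanceConfig,
    Metric,
    WeightFunction,
    objective_phi,
)
from .rank_core import RankedList, RankEnsemble

__all__ = ["CEParams", "AggregationResult", "aggregate_ce", "aggregate_brute_force"]

_PROB_FLOOR = 1e-12  # keeps every item reachable at every position


@dataclass(frozen=True)
class CEParams:
    """Cross-entropy search parameters.

    ``n_samples=None`` resolves to ``max(200, 10 * n)`` at run time.
    ``seed`` is mandatory: every run is reproducible bit-for-bit.
    """

    seed: int
    n_samples: int | None = None
    elite_fraction: float = 0.1
    smoothing: float = 0.25
    max_iterations: int = 100
    stagnation_limit: int = 15

    def __post_init__(self) -> None:
        if not (0.0 < self.elite_fraction < 1.0):
            raise ConfigurationError("elite_fraction must be in (0, 1)")
        if not (0.0 < self.smoothing <= 1.0):
            raise ConfigurationError("smoothing must be in (0, 1]")
        if self.max_iterations < 1 or self.stagnation_limit < 1:
            raise ConfigurationError(
                "max_iterations and stagnation_limit must be >= 1"
            )
        if self.n_samples is not None:
            if self.n_samples < 1:
                raise ConfigurationError("n_samples must be >= 1")
            if math.ceil(self.elite_fraction * self.n_samples) < 1:
                raise ConfigurationError("elite set would be empty")

    def resolve(self, n: int) -> "CEParams":
        if self.n_samples is not None:
            return self
        return replace(self, n_samples=max(200, 10 * n))


@dataclass(frozen=True)
class AggregationResult:
    """Consensus list delta*, its objective Phi, and full provenance."""

    best_list: RankedList
    objective: float
    method: str  # "cross_entropy" | "brute_force"
    trace: tuple[dict, ...] = ()
    params: CEParams | None = None
    cfg: DistanceConfig = field(default_factory=DistanceConfig)


def _ensemble_arrays(
    ensemble: RankEnsemble, cfg: DistanceConfig
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(sorted item ids, rank matrix (m, n), weight vector (m,))."""
    if cfg.metric is Metric.WEIGHTED_FOOTRULE and (
        cfg.weight_function is WeightFunction.NORMALIZED_SCORE
    ):
        raise ConfigurationError(
            "aggregation supports weighted_footrule only with the "
            "linear_rank weight function: a candidate permutation carries "
            "no scores to normalize"
        )
    universe = sorted(ensemble.universe)
    for L in ensemble.lists:
        if L.universe != frozenset(universe):
            diff = sorted(L.universe ^ frozenset(universe))
            raise ConfigurationError(
                f"list {L.name!r} is not a permutation of the ensemble "
                f"universe; difference: {diff}"
            )
    idx = {t: i for i, t in enumerate(universe)}
    m, n = len(ensemble.lists), len(universe)
    R = np.empty((m, n), dtype=np.float64)
    for li, L in enumerate(ensemble.lists):
        for t in L.items:
            R[li, idx[t]] = L.rank(t)
    w = np.array([ensemble.weight(L.name) for L in ensemble.lists])
    return universe, R, w


def _phi_batch(
    cand_ranks: np.ndarray, R: np.ndarray, w: np.ndarray, cfg: DistanceConfig
) -> np.ndarray:
    """Phi for a batch of candidate rank vectors, shape (S, n) -> (S,)."""
    diffs = np.abs(cand_ranks[:, None, :] - R[None, :, :])
    if cfg.metric is Metric.WEIGHTED_FOOTRULE:
        # linear_rank M: |M(r1) - M(r2)| = |r1 - r2| / n
        n = cand_ranks.shape[1]
        diffs = diffs * diffs / n
    return diffs.sum(axis=2) @ w


def _sample_permutations_numpy(P: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Vectorized reference sampler; semantics identical to the jitted one."""
    n = P.shape[0]
    n_samples = U.shape[0]
    perms = np.empty((n_samples, n), dtype=np.int64)
    avail = np.ones((n_samples, n), dtype=bool)
    rows = np.arange(n_samples)
    for pos in range(n):
        probs = np.where(avail, P[:, pos][None, :], 0.0)
        totals = probs.sum(axis=1)
        cum = np.cumsum(probs, axis=1)
        u = U[:, pos] * totals
        choice = (cum < u[:, None]).sum(axis=1)
        np.clip(choice, 0, n - 1, out=choice)
        # float round-off can land on an exhausted item; repair those rows
        bad = ~avail[rows, choice]
        if bad.any():
            for s in np.flatnonzero(bad):
                choice[s] = np.flatnonzero(avail[s])[-1]
        perms[:, pos] = choice
        avail[rows, choice] = False
    return perms


def _sample_permutations_loops(P: np.ndarray, U: np.ndarray) -> np.ndarray:
    # plain-loop kernel, jitted by numba when available; keeps the unused
    # items in ascending index order so selection semantics match the
    # vectorized reference exactly
    n = P.shape[0]
    n_samples = U.shape[0]
    perms = np.empty((n_samples, n), dtype=np.int64)
    left = np.empty(n, dtype=np.int64)
    for s in range(n_samples):
        for i in range(n):
            left[i] = i
        m = n
        for pos in range(n):
            total = 0.0
            for j in range(m):
                total += P[left[j], pos]
            r = U[s, pos] * total
            acc = 0.0
            sel = m - 1  # round-off: fall back to the last available item
            for j in range(m):
                acc += P[left[j], pos]
                if acc >= r:
                    sel = j
                    break
            perms[s, pos] = left[sel]
            for j in range(sel, m - 1):
                left[j] = left[j + 1]
            m -= 1
    return perms


def _swap_polish_loops(
    cand_ranks: np.ndarray, R: np.ndarray, w: np.ndarray, weighted: bool
) -> np.ndarray:
    """Best-found pairwise-swap descent on the candidate rank vector.

    Exchanging the positions of two items changes only their own terms of
    Phi, so each swap is O(m) to evaluate; descent runs until no swap
    improves.  Refining the sampler's incumbent this way is the usual
    memetic step for cross-entropy searches over permutations.
    """
    n = cand_ranks.shape[0]
    m = R.shape[0]
    cr = cand_ranks.copy()
    improved = True
    while improved:
        improved = False
        for a in range(n):
            for b in range(a + 1, n):
                ra = cr[a]
                rb = cr[b]
                delta = 0.0
                for i in range(m):
                    da_new = abs(rb - R[i, a])
                    db_new = abs(ra - R[i, b])
                    da_old = abs(ra - R[i, a])
                    db_old = abs(rb - R[i, b])
                    if weighted:
                        delta += w[i] * (
                            da_new * da_new + db_new * db_new
                            - da_old * da_old - db_old * db_old
                        ) / n
                    else:
                        delta += w[i] * (da_new + db_new - da_old - db_old)
                if delta < -1e-9:
                    cr[a] = rb
                    cr[b] = ra
                    improved = True
    return cr


try:  # the jitted kernels are ~10x faster at the 107-item scale
    from numba import njit

    _sample_permutations_fast = njit(cache=True)(_sample_permutations_loops)
    _swap_polish = njit(cache=True)(_swap_polish_loops)
except ImportError:  # pragma: no cover - numba is a hard dep in practice
    _sample_permutations_fast = _sample_permutations_numpy
    _swap_polish = _swap_polish_loops


def _sample_permutations(
    P: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample permutations position-by-position from column distributions.

    Returns an (n_samples, n) array; row s lists item indices best-first.
    Uniform draws are taken up front so the jitted and numpy kernels give
    bit-identical results for the same seed.
    """
    U = rng.random((n_samples, P.shape[0]))
    return _sample_permutations_fast(P, U)


def aggregate_ce(
    ensemble: RankEnsemble,
    cfg: DistanceConfig | None = None,
    params: CEParams | None = None,
) -> AggregationResult:
    """Cross-entropy Monte Carlo minimization of Phi over permutations.

    Fully reproducible given ``params.seed``; the trace records, per
    iteration, the incumbent (best-so-far) and elite-mean objectives.
    """
    cfg = cfg or DistanceConfig()
    if params is None:
        raise ConfigurationError("CEParams with an explicit seed is required")
    universe, R, w = _ensemble_arrays(ensemble, cfg)
    n = len(universe)
    params = params.resolve(n)
    rng = np.random.default_rng(params.seed)

    if n == 1:
        best = RankedList(name="consensus", items=(universe[0],))
        return AggregationResult(
            best_list=best,
            objective=objective_phi(best, ensemble, cfg),
            method="cross_entropy",
            params=params,
            cfg=cfg,
        )

    P = np.full((n, n), 1.0 / n)
    n_elite = math.ceil(params.elite_fraction * params.n_samples)
    best_perm: np.ndarray | None = None
    best_phi = np.inf
    stagnant = 0
    trace: list[dict] = []

    for it in range(params.max_iterations):
        perms = _sample_permutations(P, params.n_samples, rng)
        cand_ranks = np.argsort(perms, axis=1).astype(np.float64) + 1.0
        phi = _phi_batch(cand_ranks, R, w, cfg)
        order = np.argsort(phi, kind="stable")
        elite = perms[order[:n_elite]]

        if phi[order[0]] < best_phi - 1e-12:
            best_phi = float(phi[order[0]])
            best_perm = perms[order[0]].copy()
            stagnant = 0
        else:
            stagnant += 1

        freq = np.zeros_like(P)
        pos_idx = np.broadcast_to(np.arange(n), elite.shape)
        np.add.at(freq, (elite.ravel(), pos_idx.ravel()), 1.0)
        freq /= n_elite
        P = (1.0 - params.smoothing) * P + params.smoothing * freq
        P = np.maximum(P, _PROB_FLOOR)
        P /= P.sum(axis=0, keepdims=True)

        trace.append(
            {
                "iteration": it + 1,
                "best_phi": best_phi,
                "elite_mean_phi": float(phi[order[:n_elite]].mean()),
            }
        )
        if stagnant >= params.stagnation_limit:
            break

    assert best_perm is not None
    # memetic refinement: pairwise-swap descent from the incumbent; it can
    # only lower Phi, never drop below the global optimum
    inc_ranks = np.argsort(best_perm).astype(np.float64) + 1.0
    polished = _swap_polish(
        inc_ranks, R, w, cfg.metric is Metric.WEIGHTED_FOOTRULE
    )
    order = np.argsort(polished)
    best = RankedList(
        name="consensus", items=tuple(universe[i] for i in order)
    )
    objective = objective_phi(best, ensemble, cfg)
    assert objective <= best_phi + 1e-9
    return AggregationResult(
        best_list=best,
        objective=objective,
        method="cross_entropy",
        trace=tuple(trace),
        params=params,
        cfg=cfg,
    )


def aggregate_brute_force(
    ensemble: RankEnsemble, cfg: DistanceConfig | None = None
) -> AggregationResult:
    """Exact minimizer of Phi by exhaustive enumeration (n <= 8).

    Ties are broken deterministically: the lexicographically smallest
    optimal permutation of item ids is returned.
    """
    cfg = cfg or DistanceConfig()
    universe, R, w = _ensemble_arrays(ensemble, cfg)
    n = len(universe)
    if n > 8:
        raise ConfigurationError(
            f"brute force is guarded to n <= 8 (got n = {n}); "
            f"use aggregate_ce for larger universes"
        )
    best_perm: tuple[int, ...] | None = None
    best_phi = np.inf
    # itertools yields permutations of sorted ids in lexicographic order,
    # so the first strict improvement is automatically the lex-smallest tie.
    chunk: list[tuple[int, ...]] = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 5040:
            arr = np.asarray(chunk, dtype=np.intp)
            ranks = np.argsort(arr, axis=1).astype(np.float64) + 1.0
            phi = _phi_batch(ranks, R, w, cfg)
            k = int(np.argmin(phi))
            if phi[k] < best_phi - 1e-12:
                best_phi = float(phi[k])
                best_perm = chunk[k]
            chunk = []
    if chunk:
        arr = np.asarray(chunk, dtype=np.intp)
        ranks = np.argsort(arr, axis=1).astype(np.float64) + 1.0
        phi = _phi_batch(ranks, R, w, cfg)
        k = int(np.argmin(phi))
        if phi[k] < best_phi - 1e-12:
            best_phi = float(phi[k])
            best_perm = chunk[k]
    assert best_perm is not None
    best = RankedList(
        name="consensus", items=tuple(universe[i] for i in best_perm)
    )
    objective = objective_phi(best, ensemble, cfg)
    assert abs(objective - best_phi) < 1e-9
    return AggregationResult(
        best_list=best, objective=objective, method="brute_force", cfg=cfg
    )
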