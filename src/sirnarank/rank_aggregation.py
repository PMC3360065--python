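"""Consensus ranking by weighted Kendall distance minimisation.

Given m ordered lists L_1..L_m over one universe of k items (here: the
features shared by the three norm-specific rankings) find the "super"-list

    δ* = argmin_δ  Σ_i w_i · d_K(δ, L_i)

where d_K counts the unordered item pairs ranked in opposite relative order.
The search uses Cross-Entropy Monte Carlo: permutations are sampled from an
item × position probability matrix, the matrix is re-estimated from the
elite fraction each iteration and smoothed, until the best objective
stagnates.  A factorial brute-force oracle (k ≤ 8) is provided for
verification.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ranking import RankedFeatureList


def kendall_distance(a: Sequence[int], b: Sequence[int]) -> int:
    """Number of discordant unordered pairs between two permutations of the
    same set.  0 iff equal; maximum k(k−1)/2 for reversed lists."""
    if set(a) != set(b) or len(a) != len(b):
        raise ValueError("arguments must be permutations of the same set")
    pos_b = {item: i for i, item in enumerate(b)}
    mapped = [pos_b[item] for item in a]
    k = len(mapped)
    return sum(
        1 for i in range(k) for j in range(i + 1, k) if mapped[i] > mapped[j]
    )


@dataclass
class AggregationProblem:
    """m input orderings with importance weights over one item universe."""

    lists: list[list[int]]
    weights: np.ndarray | None = None  # default: uniform 1/m

    def __post_init__(self):
        if not self.lists:
            raise ValueError("need at least one list")
        universe = set(self.lists[0])
        for lst in self.lists:
            if set(lst) != universe or len(lst) != len(universe):
                raise ValueError("lists must be permutations of one universe")
        if self.weights is None:
            self.weights = np.full(len(self.lists), 1.0 / len(self.lists))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.lists) or (self.weights < 0).any():
            raise ValueError("weights must be non-negative, one per list")
        if self.weights.sum() <= 0:
            raise ValueError("weights must not all be zero")

    @property
    def k(self) -> int:
        return len(self.lists[0])

    @classmethod
    def from_ranked_lists(
        cls, lists: Sequence[RankedFeatureList], weights: Sequence[float] | None = None
    ) -> "AggregationProblem":
        return cls([lst.features() for lst in lists],
                   None if weights is None else np.asarray(weights, float))


def aggregation_objective(delta: Sequence[int], problem: AggregationProblem) -> float:
    """Σ_i w_i · d_K(δ, L_i)."""
    return float(sum(w * kendall_distance(delta, lst)
                     for w, lst in zip(problem.weights, problem.lists)))


def brute_force_aggregate(problem: AggregationProblem) -> tuple[list[int], float]:
    """Exhaustive k! search; oracle for the CE optimiser.

    Returns the lexicographically smallest global minimiser (by item order
    within the sorted universe) and its objective.  Refuses k > 8.
    """
    if problem.k > 8:
        raise ValueError(f"brute force refuses k={problem.k} > 8")
    universe = sorted(problem.lists[0])
    best: list[int] | None = None
    best_obj = np.inf
    for perm in itertools.permutations(universe):
        obj = aggregation_objective(perm, problem)
        if obj < best_obj:
            best, best_obj = list(perm), obj
    return best, float(best_obj)


@dataclass
class CEConfig:
    pool: int | None = None  # default 10·k²
    elite_fraction: float = 0.1
    smoothing: float = 0.7  # ν: weight of the new elite-frequency estimate
    stagnation_window: int = 10
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.elite_fraction < 1.0:
            raise ValueError("elite fraction must be in (0, 1)")
        if not 0.0 < self.smoothing <= 1.0:
            raise ValueError("smoothing must be in (0, 1]")


@dataclass
class CEResult:
    delta: list[int]
    objective: float
    trace: np.ndarray  # best-so-far objective per iteration
    n_iter: int


def _sample_permutations(P: np.ndarray, pool: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``pool`` permutations from the item × position matrix P by
    sequential position filling without replacement (vectorised over the
    pool)."""
    k = P.shape[0]
    out = np.empty((pool, k), dtype=int)
    available = np.ones((pool, k), dtype=bool)
    u = rng.random((pool, k))
    for pos in range(k):
        p = np.where(available, P[:, pos][None, :], 0.0)
        totals = p.sum(axis=1, keepdims=True)
        # degenerate column: fall back to uniform over remaining items
        uniform = available / available.sum(axis=1, keepdims=True)
        p = np.where(totals > 0, p / np.where(totals > 0, totals, 1.0), uniform)
        cdf = np.cumsum(p, axis=1)
        choice = (u[:, pos][:, None] < cdf).argmax(axis=1)
        out[:, pos] = choice
        available[np.arange(pool), choice] = False
    return out


def _batch_objectives(samples: np.ndarray, int_lists: list[list[int]],
                      weights: np.ndarray) -> np.ndarray:
    """Weighted Kendall objective for a (pool, k) batch of permutations,
    vectorised: discordant pairs are counted on the position-mapped arrays."""
    pool, k = samples.shape
    iu, ju = np.triu_indices(k, 1)
    objs = np.zeros(pool)
    for w, lst in zip(weights, int_lists):
        pos = np.empty(k, dtype=int)
        pos[lst] = np.arange(k)
        mapped = pos[samples]
        objs += w * (mapped[:, iu] > mapped[:, ju]).sum(axis=1)
    return objs


def ce_aggregate(problem: AggregationProblem, config: CEConfig | None = None) -> CEResult:
    """Cross-Entropy Monte Carlo search for the consensus ordering.

    Keeps an item × position probability matrix, re-fits it to the elite
    fraction each iteration with smoothing ν, and stops once the best
    objective has been stagnant for the configured window.  The returned
    trace (best objective so far per iteration) is non-increasing.
    """
    cfg = config or CEConfig()
    k = problem.k
    universe = problem.lists[0]  # item id per index used internally
    index_of = {item: i for i, item in enumerate(universe)}
    int_lists = [[index_of[x] for x in lst] for lst in problem.lists]
    int_problem = AggregationProblem([lst for lst in int_lists],
                                     problem.weights.copy())
    pool = cfg.pool if cfg.pool is not None else 10 * k * k
    n_elite = max(1, int(np.ceil(cfg.elite_fraction * pool)))
    rng = np.random.default_rng(cfg.seed)

    P = np.full((k, k), 1.0 / k)
    best_perm = list(int_lists[0])
    best_obj = aggregation_objective(best_perm, int_problem)
    trace = []
    stagnant = 0
    it = 0
    for it in range(1, cfg.max_iter + 1):
        samples = _sample_permutations(P, pool, rng)
        objs = _batch_objectives(samples, int_lists, int_problem.weights)
        order = np.argsort(objs, kind="stable")  # ties: first-sampled wins
        elite = samples[order[:n_elite]]
        if objs[order[0]] < best_obj:
            best_obj = float(objs[order[0]])
            best_perm = list(samples[order[0]])
            stagnant = 0
        else:
            stagnant += 1
        P_new = np.zeros((k, k))
        for perm in elite:
            P_new[perm, np.arange(k)] += 1.0
        P_new /= n_elite
        P = cfg.smoothing * P_new + (1.0 - cfg.smoothing) * P
        trace.append(best_obj)
        if best_obj == 0.0 or stagnant >= cfg.stagnation_window:
            break
    return CEResult([universe[i] for i in best_perm], best_obj,
                    np.array(trace), it)


def mean_rank_list(problem: AggregationProblem) -> list[int]:
    """Diagnostic only: items ordered by their weighted mean rank across the
    input lists (the 'average ranking list' companion to the optimised δ)."""
    w = problem.weights / problem.weights.sum()
    scores: dict[int, float] = {item: 0.0 for item in problem.lists[0]}
    for wi, lst in zip(w, problem.lists):
        for r, item in enumerate(lst):
            scores[item] += wi * r
    return sorted(scores, key=lambda item: (scores[item], item))
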