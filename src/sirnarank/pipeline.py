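"""End-to-end feature-selection pipeline.

One call chains the stages: per-norm λ selection on a CV grid → per-fold
joint fits → CV-stable ranked list per norm → intersection of the three
lists → Cross-Entropy rank aggregation into a single consensus ranking.
Everything is deterministic given (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .multitask import (CVResult, Norm, SolverConfig, StackedDesign, cv_fit,
                        select_lambda)
from .rank_aggregation import AggregationProblem, CEConfig, CEResult, ce_aggregate
from .ranking import (RankedFeatureList, cv_stable_features, intersect_lists,
                      largest_gap_cut)

NORMS: tuple[Norm, ...] = ("l21", "l1inf", "trace")


@dataclass
class NormSelection:
    norm: Norm
    lam: float
    cv: CVResult
    ranked: RankedFeatureList  # full CV-stable list
    selected: RankedFeatureList  # after the largest-gap cut

    def selected_features(self) -> list[int]:
        return self.selected.features()


@dataclass
class PipelineResult:
    per_norm: dict[Norm, NormSelection]
    common_features: set[int]
    consensus: RankedFeatureList
    ce_result: CEResult

    def mean_rmse_table(self) -> dict[Norm, np.ndarray]:
        return {norm: sel.cv.mean_rmse() for norm, sel in self.per_norm.items()}


def select_features_for_norm(
    design: StackedDesign,
    norm: Norm,
    folds: int = 10,
    seed: int = 0,
    lam: float | None = None,
    grid_points: int = 20,
    solver: SolverConfig | None = None,
    zero_threshold: float = 1e-8,
) -> NormSelection:
    """λ selection (unless given), per-fold fits and the stable ranked list
    for one penalty."""
    base = solver or SolverConfig(norm=norm)
    if lam is None:
        lam, _, _ = select_lambda(design, norm, folds=folds, seed=seed,
                                  n_points=grid_points, base_config=base)
    cfg = SolverConfig(norm=norm, lam=lam, tol=base.tol, max_iter=base.max_iter,
                       loss_scaling=base.loss_scaling,
                       zero_threshold=zero_threshold,
                       intercept_row=base.intercept_row)
    cv = cv_fit(design, cfg, folds=folds, seed=seed)
    ranked = cv_stable_features([fr.W for fr in cv.per_fold],
                                zero_threshold=zero_threshold, origin=norm)
    return NormSelection(norm, lam, cv, ranked, largest_gap_cut(ranked))


def run_pipeline(
    design: StackedDesign,
    folds: int = 10,
    seed: int = 0,
    grid_points: int = 20,
    norms: tuple[Norm, ...] = NORMS,
    ce_config: CEConfig | None = None,
    solver: SolverConfig | None = None,
) -> PipelineResult:
    """Full three-norm selection + rank aggregation.

    The consensus list carries positional weights k, k−1, …, 1 (the
    aggregated ordering is what matters, not the magnitudes).
    """
    per_norm = {
        norm: select_features_for_norm(design, norm, folds=folds, seed=seed,
                                       grid_points=grid_points, solver=solver)
        for norm in norms
    }
    common, restricted = intersect_lists([per_norm[n].ranked for n in norms])
    problem = AggregationProblem.from_ranked_lists(restricted)
    ce = ce_aggregate(problem, ce_config or CEConfig(seed=seed))
    k = len(ce.delta)
    consensus = RankedFeatureList(
        [(f, float(k - i)) for i, f in enumerate(ce.delta)], origin="consensus")
    return PipelineResult(per_norm, common, consensus, ce)
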