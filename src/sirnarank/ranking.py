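"""Per-norm ranked feature lists from fitted weight matrices.

A feature matters across platforms when its row of W is non-zero: the
cross-task weight ``w_i = Σ_j |W_ij|`` is zero exactly when the feature's
regression weight is zero in every task, and its magnitude quantifies the
feature's joint importance.  Stability filtering keeps only features
selected in *every* CV fold, ranked by mean weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

Aggregation = Literal["l1", "l2"]


@dataclass
class RankedFeatureList:
    """Ordered (feature index, weight) pairs, weight strictly ordering the
    list (descending; ties broken by ascending feature index)."""

    entries: list[tuple[int, float]]
    origin: str = ""  # l21 | l1inf | trace | consensus

    def __post_init__(self):
        feats = [f for f, _ in self.entries]
        if len(feats) != len(set(feats)):
            raise ValueError("duplicate features in ranked list")
        if any(w < 0 for _, w in self.entries):
            raise ValueError("weights must be >= 0")
        order = sorted(self.entries, key=lambda e: (-e[1], e[0]))
        if order != self.entries:
            raise ValueError("entries not in canonical (weight desc, index asc) order")

    @classmethod
    def from_weights(cls, features: Sequence[int], weights: Sequence[float],
                     origin: str = "") -> "RankedFeatureList":
        entries = sorted(zip(features, (float(w) for w in weights)),
                         key=lambda e: (-e[1], e[0]))
        return cls(entries, origin)

    def features(self) -> list[int]:
        return [f for f, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self, names: dict[int, str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=["feature", "weight"])
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        if names:
            df.insert(2, "name", [names.get(f, "") for f in df["feature"]])
        return df


def feature_weights(W: np.ndarray, aggregation: Aggregation = "l1") -> np.ndarray:
    """Cross-task feature weight per row of W.

    ``l1`` (default): Σ_j |W_ij| — zero iff the whole row is zero, satisfying
    the common-feature criterion.  ``l2``: the row ℓ2 norm, same zero set.
    """
    if not np.isfinite(W).all():
        raise ValueError("W must be finite")
    if aggregation == "l1":
        return np.abs(W).sum(axis=1)
    if aggregation == "l2":
        return np.linalg.norm(W, axis=1)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def cv_stable_features(
    per_fold_W: Sequence[np.ndarray],
    zero_threshold: float = 1e-8,
    aggregation: Aggregation = "l1",
    origin: str = "",
    exclude: Sequence[int] = (0,),
) -> RankedFeatureList:
    """Features selected in **all** folds, ranked by mean cross-task weight.

    ``exclude`` removes bookkeeping rows (default: row 0, the intercept
    column) from the ranking.  An empty intersection returns an empty list
    with a warning rather than raising.
    """
    if len(per_fold_W) < 2:
        raise ValueError("need at least 2 folds for stability filtering")
    weights = np.stack([feature_weights(W, aggregation) for W in per_fold_W])
    stable = (weights > zero_threshold).all(axis=0)
    stable[list(exclude)] = False
    idx = np.flatnonzero(stable)
    if idx.size == 0:
        warnings.warn("no feature survived all folds", RuntimeWarning)
    # sort fold weights per feature before averaging so the result is
    # bit-identical under any fold ordering
    mean_w = np.sort(weights[:, idx], axis=0).mean(axis=0)
    return RankedFeatureList.from_weights(idx.tolist(), mean_w, origin=origin)


def largest_gap_cut(
    ranked: RankedFeatureList, head_fraction: float = 0.05
) -> RankedFeatureList:
    """Truncate a ranked list at the largest multiplicative weight gap.

    Group-sparse fits at a prediction-chosen λ keep, besides the jointly
    relevant features, a residue of correlated features at much smaller
    weight.  The list is cut after the position with the largest
    consecutive weight ratio w_r/w_{r+1}, with the search restricted to the
    head of the list (positions whose weight is at least ``head_fraction``
    of the top weight): weights deep in the tail approach the numerical
    zero threshold and would otherwise produce meaningless giant ratios.
    Zero-weight entries are always dropped.
    """
    entries = [e for e in ranked.entries if e[1] > 0]
    if len(entries) < 2:
        return RankedFeatureList(entries, ranked.origin)
    w_max = entries[0][1]
    head = [i for i in range(len(entries) - 1)
            if entries[i][1] >= head_fraction * w_max]
    if not head:
        return RankedFeatureList(entries, ranked.origin)
    best = max(head, key=lambda i: entries[i][1] / entries[i + 1][1])
    return RankedFeatureList(entries[: best + 1], ranked.origin)


def intersect_lists(
    lists: Sequence[RankedFeatureList],
) -> tuple[set[int], list[RankedFeatureList]]:
    """Common feature set of the per-norm lists plus each list restricted to
    it (internal order preserved) — the shared universe rank aggregation
    requires."""
    if len(lists) < 2:
        raise ValueError("need at least 2 lists")
    common = set(lists[0].features())
    for lst in lists[1:]:
        common &= set(lst.features())
    if not common:
        raise ValueError("empty intersection: rank aggregation undefined")
    restricted = [
        RankedFeatureList([e for e in lst.entries if e[0] in common], lst.origin)
        for lst in lists
    ]
    return common, restricted
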