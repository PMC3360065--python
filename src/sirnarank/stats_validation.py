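"""Significance and validation analyses for selected siRNA features.

All associations are computed against the **product level** (remaining
mRNA/protein fraction): a *negative* correlation means the feature increases
silencing potency.  "Potent" means product level < 0.3 throughout.

Contents: one-tailed Welch (unequal-variance) t-tests, per-feature
correlation/p-value tables, the GC-content window scan that locates the
potency-enriched GC range, position-specific motif profiles, and repeated
2-fold ridge-regression RMSE comparison of two candidate feature sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureSchema, build_default_schema, gc_content
from .io_datasets import SiRNARecord

POTENCY_THRESHOLD = 0.3
SIGNIFICANCE_LEVEL = 0.05


# ---------------------------------------------------------------------------
# Welch t-test

def welch_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: Literal["less", "greater"] = "less",
) -> tuple[float, float, float]:
    """One-tailed two-sample unequal-variance t-test.

    Returns ``(t, df, p)`` with t = (mean_a − mean_b)/√(s²_a/n_a + s²_b/n_b)
    and Welch–Satterthwaite degrees of freedom.  ``alternative='less'``
    tests mean_a < mean_b.  Groups of fewer than 2 values are rejected;
    two exactly constant equal groups get p = 0.5 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / a.size + vb / b.size
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        warnings.warn("zero variance in both groups; p from sign convention",
                      RuntimeWarning)
        if diff == 0.0:
            return 0.0, float(a.size + b.size - 2), 0.5
        t = np.inf if diff > 0 else -np.inf
        p = (0.0 if diff < 0 else 1.0) if alternative == "less" else (0.0 if diff > 0 else 1.0)
        return float(t), float(a.size + b.size - 2), p
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1))
    p = sps.t.cdf(t, df) if alternative == "less" else sps.t.sf(t, df)
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# Feature association table (correlation + significance)

@dataclass
class FeatureAssociation:
    feature: int
    name: str
    r: float | None  # Pearson R vs product level; None if undefined
    p: float | None  # one-tailed Welch p, feature-present vs absent
    n_present: int
    n_absent: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def feature_association_table(
    X: np.ndarray,
    y: np.ndarray,
    features: Sequence[int],
    schema: FeatureSchema | None = None,
) -> list[FeatureAssociation]:
    """Per-feature Pearson R and Welch p against product level.

    ``X`` is the encoded design (columns = 0-based feature rows of the
    schema), ``y`` the product levels.  For the t-test a feature is
    dichotomised at value > 0.5 for binary flags and at its median
    otherwise; the one-tailed direction follows the sign of R (testing that
    the observed shift in mean product level is real).  A constant feature
    column yields ``r = p = None`` rather than an error.
    """
    schema = schema or build_default_schema()
    y = np.asarray(y, dtype=float)
    out = []
    for f in features:
        col = X[:, f]
        name = schema[f + 1].name
        r = _pearson(col, y)
        if r is None:
            out.append(FeatureAssociation(f, name, None, None, 0, 0))
            continue
        cut = 0.5 if set(np.unique(col)) <= {0.0, 1.0} else float(np.median(col))
        present = col > cut
        ya, yb = y[present], y[~present]
        if ya.size < 2 or yb.size < 2:
            out.append(FeatureAssociation(f, name, r, None, int(present.sum()),
                                          int((~present).sum())))
            continue
        _, _, p = welch_t_test(ya, yb, "less" if r < 0 else "greater")
        out.append(FeatureAssociation(f, name, r, p, int(present.sum()),
                                      int((~present).sum())))
    return out


def association_frame(assocs: list[FeatureAssociation]) -> pd.DataFrame:
    df = pd.DataFrame([vars(a) for a in assocs])
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


# ---------------------------------------------------------------------------
# GC window scan

@dataclass
class GCWindowResult:
    lower: float
    upper: float
    n_in_window: int
    fraction_potent: float | None  # None for an empty window


def gc_window_scan(
    records: Sequence[SiRNARecord],
    upper: float = 0.55,
    lower_grid: Sequence[float] | None = None,
    potency_threshold: float = POTENCY_THRESHOLD,
) -> list[GCWindowResult]:
    """Fraction of potent siRNAs inside GC windows [ℓ, upper].

    The default grid sweeps the lower bound from 0.45 down to 0.05 in 0.05
    steps with the upper bound fixed at 0.55 — the scan that identifies the
    potency-enriched GC range.  Arbitrary windows (e.g. 0.35–0.70) go
    through :func:`gc_window`.
    """
    if lower_grid is None:
        lower_grid = np.round(np.arange(0.45, 0.0, -0.05), 2)
    return [gc_window(records, float(lo), upper, potency_threshold)
            for lo in lower_grid]


def gc_window(
    records: Sequence[SiRNARecord],
    lower: float,
    upper: float,
    potency_threshold: float = POTENCY_THRESHOLD,
) -> GCWindowResult:
    if not 0.0 <= lower < upper <= 1.0:
        raise ValueError(f"bad GC window [{lower}, {upper}]")
    gc = np.array([gc_content(r.sequence) for r in records])
    y = np.array([r.efficacy for r in records])
    inside = (gc >= lower) & (gc <= upper)
    n = int(inside.sum())
    frac = float((y[inside] < potency_threshold).mean()) if n else None
    return GCWindowResult(lower, upper, n, frac)


# ---------------------------------------------------------------------------
# Position-specific motif profiles

def position_motif_profile(
    records: Sequence[SiRNARecord],
    motif: str,
    potency_threshold: float = POTENCY_THRESHOLD,
) -> pd.DataFrame:
    """Occurrence of ``motif`` by start position, split by potency.

    Two normalisations are reported per 1-based start position:

    * ``ratio_potent``    — potent occurrences / all occurrences at that
      position (enrichment of potency given the motif there);
    * ``potent_position_frac`` — that position's share of all motif
      occurrences within potent siRNAs (positional distribution).
    """
    if not 2 <= len(motif) <= 4:
        raise ValueError("motif length must be 2-4")
    L = len(records[0].sequence) if records else 19
    starts = range(1, L - len(motif) + 2)
    rows = []
    for s in starts:
        n_all = n_potent = 0
        for r in records:
            if r.sequence[s - 1 : s - 1 + len(motif)] == motif:
                n_all += 1
                if r.efficacy < potency_threshold:
                    n_potent += 1
        rows.append({"position": s, "n_all": n_all, "n_potent": n_potent,
                     "ratio_potent": n_potent / n_all if n_all else 0.0})
    df = pd.DataFrame(rows)
    total_potent = df["n_potent"].sum()
    df["potent_position_frac"] = (
        df["n_potent"] / total_potent if total_potent else 0.0)
    return df


# ---------------------------------------------------------------------------
# Ridge-regression feature-set comparison

def _ridge_fit_predict(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, alpha: float
) -> np.ndarray:
    """Closed-form ridge with unpenalised intercept on standardised columns.

    Columns are centred/scaled on the training fold only; a singular system
    at α = 0 falls back to the minimum-norm least-squares solution.
    """
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Ztr, Zte = (Xtr - mu) / sd, (Xte - mu) / sd
    yc = ytr - ytr.mean()
    d = Ztr.shape[1]
    if alpha > 0:
        w = np.linalg.solve(Ztr.T @ Ztr + alpha * np.eye(d), Ztr.T @ yc)
    else:
        try:
            w = np.linalg.solve(Ztr.T @ Ztr, Ztr.T @ yc)
        except np.linalg.LinAlgError:
            warnings.warn("singular system at alpha=0; minimum-norm fallback",
                          RuntimeWarning)
            w = np.linalg.lstsq(Ztr, yc, rcond=None)[0]
    return Zte @ w + ytr.mean()


@dataclass
class RidgeComparison:
    rmse_a: float
    rmse_b: float
    per_round_a: np.ndarray
    per_round_b: np.ndarray
    p_a_better: float  # one-tailed paired Welch-style t over rounds


def ridge_cv_compare(
    X: np.ndarray,
    y: np.ndarray,
    feature_set_a: Sequence[int],
    feature_set_b: Sequence[int],
    rounds: int = 1000,
    folds: int = 2,
    seed: int = 0,
    alpha: float = 1.0,
) -> RidgeComparison:
    """Repeated random k-fold ridge RMSE of two feature sets on one dataset.

    Each round re-splits the data, fits both feature sets with the same α
    on each training fold and scores the complementary fold; the per-round
    RMSE is the average over folds.  Bit-reproducible given (data, seed).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * folds:
        raise ValueError("dataset too small for the requested folds")
    rng = np.random.default_rng(seed)
    Xa, Xb = X[:, list(feature_set_a)], X[:, list(feature_set_b)]
    rmse_a = np.empty(rounds)
    rmse_b = np.empty(rounds)
    for r in range(rounds):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % folds
        errs_a, errs_b = [], []
        for f in range(folds):
            te = fold_of == f
            tr = ~te
            for Xs, errs in ((Xa, errs_a), (Xb, errs_b)):
                pred = _ridge_fit_predict(Xs[tr], y[tr], Xs[te], alpha)
                errs.append(np.sqrt(np.mean((pred - y[te]) ** 2)))
        rmse_a[r], rmse_b[r] = np.mean(errs_a), np.mean(errs_b)
    diff = rmse_a - rmse_b
    if diff.std(ddof=1) == 0.0:
        p = 0.5 if diff.mean() == 0 else (0.0 if diff.mean() < 0 else 1.0)
    else:
        t = diff.mean() / (diff.std(ddof=1) / np.sqrt(rounds))
        p = float(sps.t.cdf(t, rounds - 1))  # one-tailed: A better (smaller RMSE)
    return RidgeComparison(float(rmse_a.mean()), float(rmse_b.mean()),
                           rmse_a, rmse_b, p)


def paired_feature_set_test(
    rmse_a: Sequence[float], rmse_b: Sequence[float]
) -> tuple[float, float]:
    """One-tailed paired t-test across datasets that set A's mean RMSEs are
    smaller than set B's.  Returns (t, p)."""
    a = np.asarray(rmse_a, float)
    b = np.asarray(rmse_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired values")
    d = a - b
    t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
    return float(t), float(sps.t.cdf(t, d.size - 1))
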