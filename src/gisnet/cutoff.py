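"""Cutoff optimization and score-distribution comparison.

Given paired quantitative GCR rates (fold over wild type, from fluctuation
assays) and semi-quantitative GCR strain scores, an optimal score cutoff
``c*`` is chosen by maximising the cost function ``w1*SENS + w2*SPEC`` over
candidate cutoffs, with the positive class defined as strains whose rate is
at least ``rate_fold_threshold`` (default 3) times the wild-type rate.
Weighting sensitivity higher than specificity (w1=2, w2=1 by default)
reflects that false positives can be cleaned up by follow-up rate
measurements while false negatives are lost.

A Monte-Carlo two-sample Kolmogorov-Smirnov test on the discrete 0-5 patch
score support compares a mutant's patch-score distribution with the control
strain's, using permutation of the pooled sample as the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

SCORE_SUPPORT = np.arange(6)


@dataclass(frozen=True)
class CutoffConfig:
    w1: float = 2.0
    w2: float = 1.0
    rate_fold_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0 or self.w1 + self.w2 <= 0:
            raise ValueError("weights must be >= 0 with w1 + w2 > 0")
        if self.rate_fold_threshold <= 0:
            raise ValueError("rate_fold_threshold must be > 0")


@dataclass(frozen=True)
class CutoffEvaluation:
    """Confusion counts and the cost at one candidate cutoff."""

    cutoff: float
    tp: int
    fn: int
    tn: int
    fp: int
    sens: float
    spec: float
    cost: float


@dataclass(frozen=True)
class DiscreteKSResult:
    statistic: float
    p_value: float
    n_mc: int


def _classes(pairs: pd.DataFrame, config: CutoffConfig) -> np.ndarray:
    folds = pairs["rate_fold"].to_numpy(dtype=float)
    if (folds <= 0).any():
        raise ValueError("rate_fold must be > 0")
    return folds >= config.rate_fold_threshold


def confusion_at_cutoff(
    pairs: pd.DataFrame,
    cutoff: float,
    config: CutoffConfig = CutoffConfig(),
) -> CutoffEvaluation:
    """Confusion counts, SENS, SPEC and cost at one cutoff.

    A strain is *called* positive iff its score >= cutoff; it *is* positive
    iff its rate fold >= the threshold. One consistent ``>=`` call rule is
    used for all four cells so they partition the data.
    """
    if pairs.empty:
        raise ValueError("pairs table is empty")
    positive = _classes(pairs, config)
    called = pairs["score"].to_numpy(dtype=float) >= cutoff
    tp = int((positive & called).sum())
    fn = int((positive & ~called).sum())
    tn = int((~positive & ~called).sum())
    fp = int((~positive & called).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    cost = config.w1 * sens + config.w2 * spec
    return CutoffEvaluation(float(cutoff), tp, fn, tn, fp, sens, spec, cost)


def candidate_cutoffs(scores: Sequence[float]) -> np.ndarray:
    """Midpoints between consecutive distinct observed scores, plus
    sentinels below the minimum and above the maximum."""
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))


def optimal_cutoff(
    pairs: pd.DataFrame,
    config: CutoffConfig = CutoffConfig(),
) -> tuple[float, CutoffEvaluation]:
    """Cutoff maximising ``w1*SENS + w2*SPEC`` on the candidate grid.

    Ties in cost are broken toward the lowest cutoff, favouring
    sensitivity. Requires at least one strain in each class.
    """
    positive = _classes(pairs, config)
    if positive.all() or not positive.any():
        raise ValueError("need >= 1 positive and >= 1 negative pair")
    best: CutoffEvaluation | None = None
    for c in candidate_cutoffs(pairs["score"]):
        ev = confusion_at_cutoff(pairs, c, config)
        if best is None or ev.cost > best.cost + 1e-12:
            best = ev
    assert best is not None
    return best.cutoff, best


def roc_curve(
    pairs: pd.DataFrame,
    config: CutoffConfig = CutoffConfig(),
) -> pd.DataFrame:
    """ROC points (FPR, TPR) over the candidate cutoff grid.

    Rows are ordered by increasing cutoff, so (1, 1) comes first and (0, 0)
    last; TPR is nonincreasing and FPR nonincreasing along the rows.
    """
    positive = _classes(pairs, config)
    if positive.all() or not positive.any():
        raise ValueError("need >= 1 positive and >= 1 negative pair")
    rows = []
    for c in candidate_cutoffs(pairs["score"]):
        ev = confusion_at_cutoff(pairs, c, config)
        rows.append(
            {"cutoff": c, "fpr": 1.0 - ev.spec, "tpr": ev.sens, "cost": ev.cost}
        )
    return pd.DataFrame(rows)


def roc_auc(roc: pd.DataFrame) -> float:
    """Trapezoidal area under a :func:`roc_curve` table."""
    fpr = roc["fpr"].to_numpy()[::-1]
    tpr = roc["tpr"].to_numpy()[::-1]
    return float(np.trapezoid(tpr, fpr))


def _row_cdfs(values: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Row-wise empirical CDFs of an integer matrix on a small support."""
    counts = np.stack([(values == c).sum(axis=1) for c in support], axis=1)
    return np.cumsum(counts, axis=1) / values.shape[1]


def ks_statistic_discrete(
    sample_a: Sequence[int], sample_b: Sequence[int]
) -> float:
    """Supremum distance between the two empirical CDFs on {0..5}."""
    a = np.asarray(sample_a, dtype=int)[None, :]
    b = np.asarray(sample_b, dtype=int)[None, :]
    return float(np.abs(_row_cdfs(a, SCORE_SUPPORT) - _row_cdfs(b, SCORE_SUPPORT)).max())


def ks_discrete_test(
    sample_a: Sequence[int],
    sample_b: Sequence[int],
    n_mc: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> DiscreteKSResult:
    """Two-sample KS test on the discrete patch-score support.

    The null distribution of D is generated by Monte-Carlo permutation of
    the pooled sample; the p-value uses the add-one convention
    ``(#{D_perm >= D_obs} + 1) / (n_mc + 1)`` and is therefore never 0.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    a = np.asarray(sample_a, dtype=int)
    b = np.asarray(sample_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    for x in (a, b):
        if ((x < 0) | (x > 5)).any():
            raise ValueError("patch scores must lie in {0..5}")
    d_obs = ks_statistic_discrete(a, b)
    if rng is None:
        rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    na = a.size
    n_ge = 0
    chunk = max(1, min(n_mc, 4_000_000 // max(pooled.size, 1)))
    done = 0
    while done < n_mc:
        m = min(chunk, n_mc - done)
        perms = rng.permuted(np.tile(pooled, (m, 1)), axis=1)
        cdf_a = _row_cdfs(perms[:, :na], SCORE_SUPPORT)
        cdf_b = _row_cdfs(perms[:, na:], SCORE_SUPPORT)
        d_perm = np.abs(cdf_a - cdf_b).max(axis=1)
        n_ge += int((d_perm >= d_obs - 1e-12).sum())
        done += m
    p = (n_ge + 1) / (n_mc + 1)
    return DiscreteKSResult(d_obs, float(p), n_mc)
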