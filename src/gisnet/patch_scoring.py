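"""Semi-quantitative scoring of GCR patch tests.

A patch test replica-plates a patch of cells onto double-selective media;
each papilla is a colony founded by an independent gross-chromosomal-
rearrangement (GCR) event lineage. Papillae counts are converted to a
categorical 0-5 patch score, and the scores of all independent patches of
one genotype in one assay are averaged into the *GCR strain score*.

Patches that failed to grow carry the :data:`NO_GROWTH` sentinel and are
excluded from averages; a strain whose patches all failed is undefined and
flagged so it can be dropped from downstream analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class _NoGrowth:
    """Sentinel for patches that did not grow. Never enters averages."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NO_GROWTH"


NO_GROWTH = _NoGrowth()

#: Upper papillae-count bounds (inclusive) for scores 0..4; anything larger,
#: or an explicit lawn, scores 5. 150 and 1000 delimit the "countable" and
#: "too many to count" bands.
DEFAULT_BANDS: tuple[int, int, int, int, int] = (0, 5, 15, 150, 1000)


@dataclass(frozen=True)
class StrainScore:
    """Mean of the valid categorical patch scores of one genotype x assay."""

    score: float | None
    n_valid_patches: int
    n_no_growth: int
    low_replicates: bool = False

    @property
    def defined(self) -> bool:
        return self.score is not None


def score_patch(
    papillae_count: int | None = None,
    grew: bool = True,
    lawn: bool = False,
    bands: Sequence[int] = DEFAULT_BANDS,
) -> int | _NoGrowth:
    """Assign the categorical 0-5 score to a single patch.

    Parameters
    ----------
    papillae_count
        Number of papillae on the patch; ignored when ``lawn`` or not ``grew``.
    grew
        Whether the patch grew at all; non-growing patches return
        :data:`NO_GROWTH`.
    lawn
        Confluent lawn of papillae covering the patch -> score 5.
    bands
        Five inclusive upper bounds for scores 0..4.
    """
    if not grew:
        return NO_GROWTH
    if lawn:
        return 5
    if papillae_count is None:
        raise ValueError("papillae_count required for a grown, non-lawn patch")
    if papillae_count < 0:
        raise ValueError(f"papillae_count must be >= 0, got {papillae_count}")
    for score, upper in enumerate(bands):
        if papillae_count <= upper:
            return score
    return 5


def strain_score(
    patch_scores: Iterable[int | _NoGrowth],
    min_patches: int = 3,
) -> StrainScore:
    """Average valid patch scores into a GCR strain score.

    NO_GROWTH entries are counted but excluded from the mean; when every
    patch failed the score is undefined (``score=None``) so the strain can
    be ignored downstream. Fewer than ``min_patches`` valid patches raises
    a warning and sets ``low_replicates``.
    """
    scores = list(patch_scores)
    if not scores:
        raise ValueError("patch_scores must be nonempty")
    valid = [s for s in scores if s is not NO_GROWTH]
    for s in valid:
        if not 0 <= s <= 5:
            raise ValueError(f"patch score out of range: {s}")
    n_no_growth = len(scores) - len(valid)
    if not valid:
        return StrainScore(None, 0, n_no_growth)
    low = len(valid) < min_patches
    if low:
        warnings.warn(
            f"only {len(valid)} valid patches (< {min_patches})",
            stacklevel=2,
        )
    return StrainScore(float(np.mean(valid)), len(valid), n_no_growth, low)


def score_patch_table(
    patches: pd.DataFrame,
    bands: Sequence[int] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Vectorised :func:`score_patch` over a papillae table.

    Expects columns ``papillae_count`` and ``grew`` (plus arbitrary id
    columns); returns a copy with a ``patch_score`` column where NO_GROWTH
    is encoded as NaN (the strain-score aggregation treats NaN as the
    sentinel).
    """
    counts = patches["papillae_count"].to_numpy()
    grew = patches["grew"].to_numpy(dtype=bool)
    if (counts[grew] < 0).any():
        raise ValueError("negative papillae_count")
    edges = np.asarray(bands)
    score = np.searchsorted(edges, counts, side="left").astype(float)
    score[~grew] = np.nan
    out = patches.copy()
    out["patch_score"] = score
    return out


def strain_score_table(
    scored_patches: pd.DataFrame,
    by: Sequence[str] = ("query_gene", "bait_gene", "assay"),
    min_patches: int = 3,
) -> pd.DataFrame:
    """Aggregate per-patch scores into strain scores.

    ``scored_patches`` must contain ``patch_score`` (NaN = no growth) and
    the grouping columns. Returns one row per group with ``score`` (NaN when
    undefined), ``n_valid``, ``n_no_growth`` and ``low_replicates``.
    """
    by = list(by)
    g = scored_patches.groupby(by, sort=True)["patch_score"]
    out = g.agg(
        score="mean",
        n_valid="count",
        n_no_growth=lambda s: int(s.isna().sum()),
    ).reset_index()
    out["low_replicates"] = out["n_valid"] < min_patches
    return out
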