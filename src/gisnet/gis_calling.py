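"""Calling Genome Instability Suppressing (GIS) genes per assay.

A gene is flagged as suppressing GCRs in an assay when its single-mutant
strain score is at least ``delta`` (default 0.4) above the wild-type
control score for that assay. Quantitative rate measurements override the
score rule in both directions: a measured rate fold below the threefold
threshold removes a score-flagged gene, and a fold at or above threefold
flags a gene regardless of its score. Previously published GIS genes can
be merged in as a prior list.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SUPPRESSES = "suppresses"
NO_EFFECT = "no_effect"
UNTESTED = "untested"


@dataclass(frozen=True)
class CompletenessEstimate:
    estimated_missed: float
    estimated_pct_identified: float


def call_gis_single(
    strain_scores: pd.DataFrame,
    wt_scores: Mapping[str, float],
    rates: pd.DataFrame | None = None,
    prior_genes: Mapping[str, Iterable[str]] | None = None,
    delta: float = 0.4,
    fold_threshold: float = 3.0,
) -> pd.DataFrame:
    """Per-assay GIS calls from single-mutant strain scores.

    Parameters
    ----------
    strain_scores
        Columns ``gene``, ``assay``, ``score`` (NaN = undefined / strain
        could not be scored).
    wt_scores
        Per-assay wild-type control score; every assay in ``strain_scores``
        must be present.
    rates
        Optional columns ``gene``, ``assay``, ``rate_fold`` (fold over wild
        type from fluctuation assays).
    prior_genes
        Optional mapping assay -> iterable of previously published GIS
        genes for that assay.

    Returns
    -------
    DataFrame with columns ``gene``, ``assay``, ``status`` in
    {suppresses, no_effect, untested} and ``evidence`` (``+``-joined tags).
    """
    assays = strain_scores["assay"].unique()
    missing = [a for a in assays if a not in wt_scores]
    if missing:
        raise ValueError(f"missing wild-type score for assays: {missing}")

    rate_lookup: dict[tuple[str, str], float] = {}
    if rates is not None:
        for r in rates.itertuples(index=False):
            rate_lookup[(r.gene, r.assay)] = float(r.rate_fold)

    rows = []
    seen: set[tuple[str, str]] = set()
    for r in strain_scores.itertuples(index=False):
        gene, assay, score = r.gene, r.assay, r.score
        seen.add((gene, assay))
        evidence: list[str] = []
        fold = rate_lookup.get((gene, assay))
        if score is None or (isinstance(score, float) and np.isnan(score)):
            status = UNTESTED
            evidence.append("undefined_score")
        else:
            flagged = score >= wt_scores[assay] + delta
            status = SUPPRESSES if flagged else NO_EFFECT
            if flagged:
                evidence.append("score_cutoff")
        if fold is not None:
            if fold >= fold_threshold:
                status = SUPPRESSES
                evidence.append("rate_threefold")
            else:
                if status == SUPPRESSES:
                    evidence.append("removed_rate_below_threefold")
                status = NO_EFFECT
        rows.append((gene, assay, status, evidence))

    # rate-only genes never scored in an assay still enter via the rate rule
    for (gene, assay), fold in rate_lookup.items():
        if (gene, assay) in seen:
            continue
        if fold >= fold_threshold:
            rows.append((gene, assay, SUPPRESSES, ["rate_threefold"]))

    if prior_genes:
        flagged_now = {(g, a) for g, a, s, _ in rows if s == SUPPRESSES}
        index = {(g, a): i for i, (g, a, _, _) in enumerate(rows)}
        for assay, genes in prior_genes.items():
            for gene in genes:
                key = (gene, assay)
                if key in index:
                    g, a, status, ev = rows[index[key]]
                    rows[index[key]] = (g, a, SUPPRESSES, ev + ["prior_literature"])
                elif key not in flagged_now:
                    rows.append((gene, assay, SUPPRESSES, ["prior_literature"]))

    return pd.DataFrame(
        [(g, a, s, "+".join(ev)) for g, a, s, ev in rows],
        columns=["gene", "assay", "status", "evidence"],
    )


def assay_overlap(calls: pd.DataFrame) -> pd.DataFrame:
    """Count genes suppressing exactly each nonempty subset of assays.

    The counts over all subsets partition the genes flagged in >= 1 assay,
    so per-assay totals are recoverable by marginalising over the subsets
    containing that assay (the Venn-diagram cells).
    """
    assays = sorted(calls["assay"].unique())
    if not assays:
        raise ValueError("calls table contains no assays")
    hit = calls[calls["status"] == SUPPRESSES]
    per_gene = hit.groupby("gene")["assay"].agg(lambda s: frozenset(s))
    cells = []
    for subset in chain.from_iterable(
        combinations(assays, k) for k in range(1, len(assays) + 1)
    ):
        fs = frozenset(subset)
        n = int((per_gene == fs).sum())
        cells.append({"assays": "+".join(sorted(subset)), "n_genes": n})
    return pd.DataFrame(cells)


def screen_completeness(
    hits_in_random_sample: int,
    n_random_screened: int,
    total_pool: int,
    n_tested: int,
    n_identified: int,
) -> CompletenessEstimate:
    """Extrapolate how many suppressor genes the candidate-based screen
    missed, from a random re-screen of deletion-collection strains.

    ``estimated_missed = (total_pool - n_tested) * hits / n_random_screened``
    and the percent identified follows as
    ``100 * n_identified / (n_identified + estimated_missed)``.
    """
    if n_random_screened <= 0:
        raise ValueError("n_random_screened must be > 0")
    if total_pool < n_tested:
        raise ValueError("total_pool must be >= n_tested")
    missed = (total_pool - n_tested) * hits_in_random_sample / n_random_screened
    denom = n_identified + missed
    if denom <= 0:
        raise ValueError("no identified or missed genes to take a fraction of")
    pct = 100.0 * n_identified / denom
    return CompletenessEstimate(float(missed), float(pct))
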