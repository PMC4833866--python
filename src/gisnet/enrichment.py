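"""Randomization tests for GIS-gene-set enrichment in tumor cohorts.

Two permutation tests are implemented, both reporting the add-one rank
p-value ``(#{permutation stat >= observed} + 1) / (n_perm + 1)``:

* :func:`sscore_set_enrichment` — is a gene set enriched for genes with
  extreme S-scores? The null redraws gene sets of identical size uniformly
  without replacement from the scored pool (default 10,000 draws).
* :func:`length_normalized_mutation_enrichment` — is a gene set enriched
  for a class of mutations, controlling for coding length? Null sets are
  drawn gene by gene without replacement until the cumulative protein
  length (amino acids of the longest coding region) reaches the query
  set's total length; the last gene may overshoot and the mean overshoot
  fraction is recorded.

A same-size (length-naive) variant of the mutation test is exposed for
comparison; with length-proportional mutation burdens it is anticonservative
for long-gene sets, which is exactly the bias the length normalization
removes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cancer import LOF_CLASSES

#: named variant-class filters for per-class enrichment analyses
CLASS_PRESETS: dict[str, frozenset[str]] = {
    "lof": LOF_CLASSES,
    "deletions": frozenset({"frameshift_deletion", "inframe_deletion"}),
    "insertions": frozenset({"frameshift_insertion", "inframe_insertion"}),
    "frameshift_deletions": frozenset({"frameshift_deletion"}),
    "frameshift_insertions": frozenset({"frameshift_insertion"}),
    "nonsense": frozenset({"nonsense"}),
    "splice_site": frozenset({"splice_site"}),
    "missense": frozenset({"missense"}),
}

_PERM_CHUNK_ELEMENTS = 4_000_000


@dataclass(frozen=True)
class EnrichmentResult:
    observed_stat: float
    n_perm: int
    n_as_or_more_extreme: int
    p_value: float
    seed: int | None = None
    mean_overshoot_fraction: float | None = None


def _rank_p(n_ge: int, n_perm: int) -> float:
    return (n_ge + 1) / (n_perm + 1)


def _perm_chunks(
    rng: np.random.Generator, n_perm: int, n_genes: int
):
    chunk = max(1, _PERM_CHUNK_ELEMENTS // max(n_genes, 1))
    base = np.arange(n_genes)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        yield rng.permuted(np.tile(base, (m, 1)), axis=1)
        done += m


def sscore_set_enrichment(
    gene_scores: pd.DataFrame,
    query_set: Iterable[str],
    threshold: float = -2.0,
    direction: str = "le",
    n_perm: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Permutation enrichment of extreme S-scores in a gene set.

    ``gene_scores`` has columns ``gene`` and ``s_score``; ``direction``
    is ``"le"`` (tumor-suppressor-like, score <= threshold) or ``"ge"``
    (oncogene-like). The observed statistic is the number of extreme genes
    in the query set; the null redraws sets of the same size.
    """
    genes = gene_scores["gene"].to_numpy()
    scores = gene_scores["s_score"].to_numpy(dtype=float)
    query = list(dict.fromkeys(query_set))
    pool = set(genes)
    missing = [g for g in query if g not in pool]
    if missing:
        raise ValueError(f"query genes missing from score table: {missing[:5]}")
    if len(query) > len(genes):
        raise ValueError("query set larger than the scored gene pool")
    if direction == "le":
        extreme = scores <= threshold
    elif direction == "ge":
        extreme = scores >= threshold
    else:
        raise ValueError("direction must be 'le' or 'ge'")
    in_query = np.isin(genes, query)
    observed = int(extreme[in_query].sum())

    if rng is None:
        rng = np.random.default_rng(seed)
    k = len(query)
    n_ge = 0
    for perms in _perm_chunks(rng, n_perm, len(genes)):
        stats = extreme[perms[:, :k]].sum(axis=1)
        n_ge += int((stats >= observed).sum())
    return EnrichmentResult(
        float(observed), n_perm, n_ge, _rank_p(n_ge, n_perm), seed,
    )


def _qualifying_counts(
    mutations: pd.DataFrame,
    genes: np.ndarray,
    class_filter: str | Iterable[str],
    mononucleotide_repeat_only: bool = False,
    ndamage_threshold: int = 5,
) -> np.ndarray:
    """Per-gene counts of mutations passing the class filter."""
    if isinstance(class_filter, str):
        classes = CLASS_PRESETS.get(class_filter)
        if classes is None:
            raise ValueError(f"unknown class preset: {class_filter!r}")
    else:
        classes = frozenset(class_filter)
    if not classes:
        raise ValueError("class_filter is empty")
    m = mutations[mutations["variant_class"].isin(classes)]
    if "missense" in classes and "ndamage" in m.columns:
        keep = (m["variant_class"] != "missense") | (m["ndamage"] >= ndamage_threshold)
        m = m[keep]
    if mononucleotide_repeat_only:
        m = m[m["in_mononucleotide_repeat"].astype(bool)]
    counts = m.groupby("gene").size()
    return counts.reindex(genes, fill_value=0).to_numpy(dtype=float)


def length_normalized_mutation_enrichment(
    mutations: pd.DataFrame,
    annotations: pd.DataFrame,
    query_set: Iterable[str],
    class_filter: str | Iterable[str] = "lof",
    n_perm: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mononucleotide_repeat_only: bool = False,
    ndamage_threshold: int = 5,
    length_normalized: bool = True,
) -> EnrichmentResult:
    """Mutation-class enrichment in a gene set, normalized for coding length.

    ``annotations`` has columns ``gene`` and ``length_aa``. The observed
    statistic is the number of qualifying mutations in the query set. When
    ``length_normalized``, each null set accumulates random genes until its
    total length reaches the query set's; otherwise null sets simply match
    the query set's gene count (the naive test).
    """
    genes = annotations["gene"].to_numpy()
    lengths = annotations["length_aa"].to_numpy(dtype=float)
    if (lengths < 1).any():
        raise ValueError("protein lengths must be >= 1 amino acid")
    query = list(dict.fromkeys(query_set))
    gene_index = {g: i for i, g in enumerate(genes)}
    missing = [g for g in query if g not in gene_index]
    if missing:
        raise ValueError(f"query genes missing from annotations: {missing[:5]}")
    counts = _qualifying_counts(
        mutations, genes, class_filter, mononucleotide_repeat_only,
        ndamage_threshold,
    )
    qidx = np.array([gene_index[g] for g in query])
    observed = float(counts[qidx].sum())
    target_length = float(lengths[qidx].sum())

    if rng is None:
        rng = np.random.default_rng(seed)
    n_ge = 0
    overshoot_sum = 0.0
    for perms in _perm_chunks(rng, n_perm, len(genes)):
        if length_normalized:
            perm_lengths = lengths[perms]
            cum = np.cumsum(perm_lengths, axis=1)
            # include gene j while the cumulative length before it is < target
            before = cum - perm_lengths
            take = before < target_length
            stats = (counts[perms] * take).sum(axis=1)
            set_lengths = (perm_lengths * take).sum(axis=1)
            overshoot_sum += float(
                ((set_lengths - target_length) / target_length).sum()
            )
        else:
            stats = counts[perms[:, : len(query)]].sum(axis=1)
        n_ge += int((stats >= observed).sum())
    overshoot = overshoot_sum / n_perm if length_normalized else None
    return EnrichmentResult(
        observed, n_perm, n_ge, _rank_p(n_ge, n_perm), seed, overshoot,
    )


def mutation_set_enrichment_naive(
    mutations: pd.DataFrame,
    annotations: pd.DataFrame,
    query_set: Iterable[str],
    class_filter: str | Iterable[str] = "lof",
    n_perm: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Same-size-set permutation test without length normalization."""
    return length_normalized_mutation_enrichment(
        mutations, annotations, query_set, class_filter,
        n_perm=n_perm, seed=seed, rng=rng, length_normalized=False,
    )
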