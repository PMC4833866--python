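"""Genetic-interaction calling and the cooperating-GIS (cGIS) network.

A query x bait double mutant is called as interacting when its GCR strain
score exceeds the higher of the two single-mutant scores by at least the
single-mutant differential ``delta`` (default 0.4). Genes that interact
with at least one query but are not themselves GIS genes are cGIS genes.
Annotated complexes/pathways ("modules") are classified by whether two or
more mutated members share an interacting query mutation.

Strain-score tables use the convention that the wild-type query is labelled
``"WT"`` and the neutral control bait ``"leu2"``: the single-mutant score of
a bait is its score from the wild-type-query cross, and the single-mutant
score of a query is the score of its cross with the control bait.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

WT_QUERY = "WT"
CONTROL_BAIT = "leu2"

#: single-mutant scores at or above this come close to saturating the assay
SATURATION_SCORE = 4.5


@dataclass(frozen=True)
class InteractionCall:
    query: str
    bait: str
    assay: str
    double_score: float
    single_query_score: float
    single_bait_score: float
    differential: float
    called: bool
    saturated: bool
    testable: bool = True


def possible_pairs(n_queries: int) -> int:
    """Number of unordered pairs among ``n_queries`` mutations: n(n-1)/2."""
    if n_queries < 0:
        raise ValueError("n_queries must be >= 0")
    return n_queries * (n_queries - 1) // 2


def call_interaction(
    double_score: float,
    single_score_query: float | None,
    single_score_bait: float | None,
    delta: float = 0.4,
    saturation: float = SATURATION_SCORE,
    query: str = "",
    bait: str = "",
    assay: str = "",
) -> InteractionCall:
    """Apply the score-differential rule to one double mutant.

    An undefined single-mutant score makes the pair untestable (never
    called). Scores at or above the saturation level are flagged but calls
    are retained.
    """
    singles = (single_score_query, single_score_bait)
    if any(s is None or (isinstance(s, float) and np.isnan(s)) for s in singles):
        return InteractionCall(
            query, bait, assay, float(double_score),
            float("nan"), float("nan"), float("nan"),
            called=False, saturated=False, testable=False,
        )
    for s in (double_score, *singles):
        if not 0.0 <= s <= 5.0:
            raise ValueError(f"score out of [0, 5]: {s}")
    differential = double_score - max(singles)
    saturated = double_score >= saturation or max(singles) >= saturation
    return InteractionCall(
        query, bait, assay, float(double_score),
        float(singles[0]), float(singles[1]), float(differential),
        called=differential >= delta, saturated=saturated,
    )


def call_interactions(
    strain_scores: pd.DataFrame,
    delta: float = 0.4,
    saturation: float = SATURATION_SCORE,
    wt_query: str = WT_QUERY,
    control_bait: str = CONTROL_BAIT,
) -> pd.DataFrame:
    """Call every query x bait double mutant in a strain-score table.

    ``strain_scores`` needs columns ``query_gene``, ``bait_gene``, ``assay``
    and ``score`` (NaN = undefined). Returns one row per double mutant with
    the differential, call flag, saturation flag and testability.
    """
    key = ["query_gene", "bait_gene", "assay"]
    lut = strain_scores.set_index(key)["score"]

    def lookup(q: str, b: str, a: str) -> float:
        try:
            return float(lut.at[(q, b, a)])
        except KeyError:
            return float("nan")

    rows = []
    doubles = strain_scores[
        (strain_scores["query_gene"] != wt_query)
        & (strain_scores["bait_gene"] != control_bait)
    ]
    for r in doubles.itertuples(index=False):
        if np.isnan(r.score):
            continue  # double mutant itself unscorable
        sq = lookup(r.query_gene, control_bait, r.assay)
        sb = lookup(wt_query, r.bait_gene, r.assay)
        call = call_interaction(
            r.score, sq, sb, delta=delta, saturation=saturation,
            query=r.query_gene, bait=r.bait_gene, assay=r.assay,
        )
        rows.append(call.__dict__)
    return pd.DataFrame(rows)


def reciprocal_consistency(calls: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Compare double mutants measured in both cross orientations.

    For each gene pair present both as (a query, b bait) and (b query,
    a bait) in the same assay, reports the absolute score difference and
    whether the two call flags agree. Summary gives the mean absolute
    difference and the agreement fraction; empty when no reciprocal pairs.
    """
    idx = calls.set_index(["query", "bait", "assay"])
    rows = []
    seen: set = set()
    for key, r in idx.iterrows():
        q, b, a = key
        if (b, q, a) in idx.index and (frozenset((q, b)), a) not in seen:
            seen.add((frozenset((q, b)), a))
            other = idx.loc[(b, q, a)]
            rows.append({
                "gene_a": min(q, b),
                "gene_b": max(q, b),
                "assay": a,
                "abs_score_diff": abs(r["double_score"] - other["double_score"]),
                "calls_agree": bool(r["called"]) == bool(other["called"]),
            })
    table = pd.DataFrame(rows)
    if table.empty:
        return table, {}
    summary = {
        "mean_abs_diff": float(table["abs_score_diff"].mean()),
        "agreement": float(table["calls_agree"].mean()),
        "n_pairs": int(len(table)),
    }
    return table, summary


def identify_cgis(calls: pd.DataFrame, gis_genes: Iterable[str]) -> list[str]:
    """Baits with >= 1 called interaction that are not GIS genes."""
    gis = set(gis_genes)
    called = calls[calls["called"]]
    return sorted(set(called["bait"]) - gis)


def interaction_degrees(calls: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Called-interaction counts per query and per bait (degree tables)."""
    called = calls[calls["called"]]
    per_pair = called.drop_duplicates(["query", "bait"])
    return (
        per_pair.groupby("query").size().sort_values(ascending=False),
        per_pair.groupby("bait").size().sort_values(ascending=False),
    )


def classify_modules(
    modules: Mapping[str, Sequence[str]],
    calls: pd.DataFrame,
    tested_genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Split modules into shared-interaction (group 1) and unshared (group 2).

    A module is group 1 when at least two of its mutated members have
    called interactions and some query mutation is shared between two or
    more of them; modules whose interacting members lack any shared query,
    or with only a single interacting member, are group 2. Modules with no
    tested member are marked untested (group 0).
    """
    called = calls[calls["called"]]
    queries_by_bait: dict[str, set[str]] = {
        b: set(g["query"]) for b, g in called.groupby("bait")
    }
    tested = set(tested_genes) if tested_genes is not None else set(calls["bait"])
    rows = []
    for name, members in modules.items():
        members = list(members)
        tested_members = [m for m in members if m in tested]
        interacting = {m: queries_by_bait.get(m, set()) for m in tested_members}
        interacting = {m: qs for m, qs in interacting.items() if qs}
        if not tested_members:
            group = 0
        else:
            query_counts: dict[str, int] = {}
            for qs in interacting.values():
                for q in qs:
                    query_counts[q] = query_counts.get(q, 0) + 1
            shared = any(c >= 2 for c in query_counts.values())
            group = 1 if len(interacting) >= 2 and shared else 2
        rows.append({
            "module": name,
            "n_members": len(members),
            "n_tested": len(tested_members),
            "n_interacting": len(interacting),
            "group": group,
        })
    return pd.DataFrame(rows)


def rate_synergy(
    double_fold: float,
    fold_a: float,
    fold_b: float,
    null: str = "additive",
) -> bool:
    """Rate-based confirmation that a double mutant is synergistic.

    ``null="additive"`` calls synergy when the double-mutant rate fold
    exceeds the sum of the single-mutant folds; ``"multiplicative"`` uses
    their product.
    """
    if null == "additive":
        return double_fold > fold_a + fold_b
    if null == "multiplicative":
        return double_fold > fold_a * fold_b
    raise ValueError(f"unknown null model: {null!r}")
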