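"""Per-sample classification of GIS-gene defects in tumor cohorts.

Candidate tumor-suppressor homologs (selected by S-score, an integrated
copy-number/expression/methylation/mutation signature computed upstream)
are checked in each sample for four defect categories:

* ``lof_mutation`` — nonsense, frameshift insertion/deletion, in-frame
  insertion/deletion or splice-site variant;
* ``deleterious_missense`` — missense variant called deleterious by at
  least 5 of 6 functional-impact predictors (Ndamage >= 5);
* ``cn_reduced_low_expression`` — GISTIC thresholded copy number of -1 or
  -2 together with an expression Z-score below -2;
* ``silenced`` — promoter hypermethylation with expression Z below -2 in
  the absence of copy-number loss (GISTIC >= 0), isolating epigenetic loss
  from copy-number-driven loss.

Platforms a sample was never profiled on leave the corresponding
categories unassessed rather than negative; samples with no data on any
platform are excluded from summaries.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LOF_CLASSES = frozenset({
    "nonsense",
    "frameshift_insertion",
    "frameshift_deletion",
    "inframe_insertion",
    "inframe_deletion",
    "splice_site",
})

KNOWN_CLASSES = LOF_CLASSES | {"missense", "silent", "other"}

PLATFORMS = ("mutation", "cnv", "expression", "methylation")


def classify_mutation(
    variant_class: str,
    ndamage: int | None = None,
    ndamage_threshold: int = 5,
) -> str:
    """Classify one mutation as ``lof``, ``deleterious_missense`` or ``other``."""
    if variant_class in LOF_CLASSES:
        return "lof"
    if variant_class == "missense":
        if ndamage is not None and not np.isnan(ndamage) and ndamage >= ndamage_threshold:
            return "deleterious_missense"
        return "other"
    return "other"


def select_ts_candidates(
    annotations: pd.DataFrame,
    threshold: float = -2.0,
    borderline: float = -1.95,
    direction: str = "ts",
) -> pd.DataFrame:
    """Genes whose S-score marks them as candidate tumor suppressors.

    ``direction="ts"`` selects s_score <= borderline, reporting the strict
    (<= threshold) and borderline (between threshold and borderline) tiers
    separately; ``direction="onc"`` mirrors the rule at the positive
    thresholds for proto-oncogene signatures.
    """
    s = annotations["s_score"].to_numpy(dtype=float)
    if direction == "onc":
        s = -s
        threshold, borderline = -abs(threshold), -abs(borderline)
    strict = s <= threshold
    border = (s <= borderline) & ~strict
    out = annotations.loc[strict | border, ["gene"]].copy()
    tier = np.where(strict[strict | border], "strict", "borderline")
    out["tier"] = tier
    return out.reset_index(drop=True)


def _availability(
    availability: pd.DataFrame | None,
    samples: Iterable[str],
) -> pd.DataFrame:
    samples = list(samples)
    if availability is None:
        return pd.DataFrame(True, index=samples, columns=list(PLATFORMS))
    avail = availability.reindex(samples).fillna(False).astype(bool)
    for p in PLATFORMS:
        if p not in avail.columns:
            avail[p] = True
    return avail[list(PLATFORMS)]


def call_alterations(
    mutations: pd.DataFrame,
    cnv: pd.DataFrame,
    expression_z: pd.DataFrame,
    methylation: pd.DataFrame,
    candidate_genes: Iterable[str],
    availability: pd.DataFrame | None = None,
    z_threshold: float = -2.0,
    ndamage_threshold: int = 5,
    exclude_samples: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per sample x candidate-gene defect categories.

    ``cnv``, ``expression_z`` and ``methylation`` are samples x genes
    matrices (GISTIC integers, Z-scores and hypermethylation flags; NaN =
    not measured). ``mutations`` has columns ``sample``, ``gene``,
    ``variant_class`` and ``ndamage``. ``exclude_samples`` supports e.g.
    dropping mismatch-repair-defective cases before summarisation.

    Returns a long table with one row per (sample, gene, category).
    """
    genes = [g for g in candidate_genes]
    samples = sorted(
        set(cnv.index) | set(expression_z.index) | set(methylation.index)
        | set(mutations["sample"]),
    )
    if exclude_samples:
        drop = set(exclude_samples)
        samples = [s for s in samples if s not in drop]
    avail = _availability(availability, samples)
    assessable = avail.any(axis=1)
    samples = [s for s in samples if assessable.at[s]]

    muts = mutations[mutations["gene"].isin(genes) & mutations["sample"].isin(samples)]
    mut_cat = muts.apply(
        lambda r: classify_mutation(r["variant_class"], r.get("ndamage"), ndamage_threshold),
        axis=1,
    ) if len(muts) else pd.Series(dtype=object)

    rows = []
    lof_pairs = set()
    mis_pairs = set()
    if len(muts):
        for (r, cat) in zip(muts.itertuples(index=False), mut_cat):
            if cat == "lof":
                lof_pairs.add((r.sample, r.gene))
            elif cat == "deleterious_missense":
                mis_pairs.add((r.sample, r.gene))

    cnv_m = cnv.reindex(index=samples, columns=genes)
    z_m = expression_z.reindex(index=samples, columns=genes)
    meth_m = methylation.reindex(index=samples, columns=genes)

    for s in samples:
        has = avail.loc[s]
        for g in genes:
            cats = []
            if has["mutation"]:
                if (s, g) in lof_pairs:
                    cats.append("lof_mutation")
                if (s, g) in mis_pairs:
                    cats.append("deleterious_missense")
            gistic = cnv_m.at[s, g]
            z = z_m.at[s, g]
            meth = meth_m.at[s, g]
            if has["cnv"] and has["expression"]:
                if not np.isnan(gistic) and not np.isnan(z):
                    if gistic in (-1, -2) and z < z_threshold:
                        cats.append("cn_reduced_low_expression")
            if has["methylation"] and has["expression"] and has["cnv"]:
                if (
                    meth == meth  # not NaN
                    and bool(meth)
                    and not np.isnan(z)
                    and z < z_threshold
                    and not np.isnan(gistic)
                    and gistic >= 0
                ):
                    cats.append("silenced")
            for c in cats:
                rows.append({
                    "sample": s,
                    "gene": g,
                    "category": c,
                    "gistic": gistic,
                    "expression_z": z,
                    "hypermethylated": bool(meth) if meth == meth else False,
                })
    return pd.DataFrame(rows, columns=[
        "sample", "gene", "category", "gistic", "expression_z", "hypermethylated",
    ])


def summarize_samples(
    calls: pd.DataFrame,
    assessed_samples: Iterable[str],
) -> dict:
    """Combined per-sample alteration summary over assessed samples.

    For each mutation definition (LOF only; LOF plus predicted deleterious
    missense) the samples are partitioned into mutually exclusive
    combinations of mutation (M), reduced copy number with reduced
    expression (C) and silencing (S); fractions are over all samples with
    any platform data. Also reports the min-max number of altered genes
    per altered sample and the overall altered fraction.
    """
    samples = list(assessed_samples)
    if not samples:
        raise ValueError("no assessed samples")
    n = len(samples)

    def per_sample_sets(mut_cats: set[str]) -> dict:
        by_sample: dict[str, set[str]] = {s: set() for s in samples}
        genes_by_sample: dict[str, set[str]] = {s: set() for s in samples}
        for r in calls.itertuples(index=False):
            if r.sample not in by_sample:
                continue
            if r.category in mut_cats:
                by_sample[r.sample].add("M")
                genes_by_sample[r.sample].add(r.gene)
            elif r.category == "cn_reduced_low_expression":
                by_sample[r.sample].add("C")
                genes_by_sample[r.sample].add(r.gene)
            elif r.category == "silenced":
                by_sample[r.sample].add("S")
                genes_by_sample[r.sample].add(r.gene)
        combo_names = {
            frozenset(): "none",
            frozenset("M"): "mutation_only",
            frozenset("C"): "cn_expr_only",
            frozenset("S"): "silenced_only",
            frozenset("MC"): "mutation_and_cn",
            frozenset("MS"): "mutation_and_silenced",
            frozenset("CS"): "cn_and_silenced",
            frozenset("MCS"): "all_three",
        }
        fractions = {name: 0.0 for name in combo_names.values()}
        for s in samples:
            fractions[combo_names[frozenset(by_sample[s])]] += 1.0 / n
        counts = [len(genes_by_sample[s]) for s in samples if genes_by_sample[s]]
        return {
            "fractions": fractions,
            "fraction_altered": 1.0 - fractions["none"],
            "altered_genes_per_sample_min": min(counts) if counts else 0,
            "altered_genes_per_sample_max": max(counts) if counts else 0,
        }

    return {
        "n_samples": n,
        "lof_only": per_sample_sets({"lof_mutation"}),
        "lof_plus_missense": per_sample_sets({"lof_mutation", "deleterious_missense"}),
    }
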