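"""End-to-end synthetic pipeline with a machine-readable run manifest.

Runs: simulate screen -> patch scoring -> cutoff optimization -> GIS
calling -> interaction calling -> module classification -> simulate tumor
cohort -> alteration classification -> enrichment, writing every stage's
TSV output plus ``manifest.json`` recording parameters, seeds and output
checksums. Rerunning with the same configuration and seed reproduces every
output byte.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cancer import call_alterations, select_ts_candidates, summarize_samples
from .cutoff import CutoffConfig, optimal_cutoff, roc_auc, roc_curve
from .enrichment import (
    length_normalized_mutation_enrichment,
    sscore_set_enrichment,
)
from .gis_calling import SUPPRESSES, assay_overlap, call_gis_single
from .interactions import (
    CONTROL_BAIT,
    WT_QUERY,
    call_interactions,
    classify_modules,
    identify_cgis,
)
from .io import file_checksum, write_matrix, write_tsv
from .patch_scoring import score_patch_table, strain_score_table
from .synthetic import CancerConfig, ScreenConfig, simulate_cancer, simulate_screen


@dataclass
class PipelineConfig:
    """Stage parameters; every default is the screen/cohort analysis default."""

    delta: float = 0.4
    fold_threshold: float = 3.0
    w1: float = 2.0
    w2: float = 1.0
    z_threshold: float = -2.0
    s_score_threshold: float = -2.0
    s_score_borderline: float = -1.95
    ndamage_threshold: int = 5
    n_perm: int = 10000
    seed: int = 0
    screen: ScreenConfig | None = None
    cancer: CancerConfig | None = None


def _mean_scores(scores: pd.DataFrame) -> dict[str, float]:
    wt = scores[
        (scores["query_gene"] == WT_QUERY) & (scores["bait_gene"] == CONTROL_BAIT)
    ]
    return dict(zip(wt["assay"], wt["score"]))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages on synthetic data; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    screen_cfg = config.screen or ScreenConfig(seed=config.seed)
    cancer_cfg = config.cancer or CancerConfig(seed=config.seed + 1)

    # 1. simulate screen
    patches, truth = simulate_screen(screen_cfg)
    write_tsv(patches, out / "patches.tsv")
    write_tsv(truth.gene_folds, out / "screen_truth_folds.tsv")
    stages.append("simulate_screen")

    # 2. patch scoring
    scored = score_patch_table(patches)
    scores = strain_score_table(scored)
    write_tsv(scores, out / "strain_scores.tsv")
    stages.append("patch_scoring")

    # 3. cutoff optimization on bait singles of the first assay, using the
    # planted rate folds as the fluctuation-assay measurements
    assay0 = screen_cfg.assays[0][0]
    singles = scores[
        (scores["query_gene"] == WT_QUERY)
        & (scores["bait_gene"] != CONTROL_BAIT)
        & (scores["assay"] == assay0)
        & scores["score"].notna()
    ]
    pairs = singles.merge(
        truth.gene_folds, left_on="bait_gene", right_on="gene"
    )[["gene", "rate_fold", "score"]]
    cut_cfg = CutoffConfig(w1=config.w1, w2=config.w2,
                           rate_fold_threshold=config.fold_threshold)
    c_star, evaluation = optimal_cutoff(pairs, cut_cfg)
    roc = roc_curve(pairs, cut_cfg)
    write_tsv(roc, out / "roc.tsv")
    write_tsv(pd.DataFrame([evaluation.__dict__]), out / "cutoff.tsv")
    stages.append("cutoff_roc")

    # 4. GIS calling from bait single-mutant scores
    wt_scores = _mean_scores(scores)
    bait_scores = scores[
        (scores["query_gene"] == WT_QUERY) & (scores["bait_gene"] != CONTROL_BAIT)
    ].rename(columns={"bait_gene": "gene"})[["gene", "assay", "score"]]
    rates = truth.gene_folds.assign(assay=assay0)[["gene", "assay", "rate_fold"]]
    gis_calls = call_gis_single(
        bait_scores, wt_scores, rates=rates,
        delta=config.delta, fold_threshold=config.fold_threshold,
    )
    write_tsv(gis_calls, out / "gis_calls.tsv")
    write_tsv(assay_overlap(gis_calls), out / "assay_overlap.tsv")
    gis_genes = sorted(set(gis_calls.loc[gis_calls["status"] == SUPPRESSES, "gene"]))
    stages.append("gis_calling")

    # 5. interaction calling
    calls = call_interactions(scores, delta=config.delta)
    write_tsv(calls, out / "interactions.tsv")
    cgis = identify_cgis(calls, gis_genes)
    (out / "cgis_genes.txt").write_text("\n".join(cgis) + "\n")
    stages.append("interaction_calling")

    # 6. module classification over synthetic three-gene modules
    baits = sorted(set(calls["bait"]))
    modules = {
        f"module{m:03d}": baits[i : i + 3]
        for m, i in enumerate(range(0, len(baits) - 2, 3), start=1)
    }
    module_table = classify_modules(modules, calls)
    write_tsv(module_table, out / "modules.tsv")
    stages.append("module_classification")

    # 7. simulate tumor cohort
    tables, cancer_truth = simulate_cancer(cancer_cfg)
    write_tsv(tables["mutations"], out / "mutations.tsv")
    write_matrix(tables["cnv"], out / "cnv.tsv")
    write_matrix(tables["expression_z"], out / "expression_z.tsv")
    write_matrix(tables["methylation"], out / "methylation.tsv")
    write_tsv(tables["annotations"], out / "gene_annotations.tsv")
    write_matrix(tables["availability"], out / "availability.tsv")
    stages.append("simulate_cancer")

    # 8. alteration classification + combined summary
    candidates = select_ts_candidates(
        tables["annotations"],
        threshold=config.s_score_threshold,
        borderline=config.s_score_borderline,
    )["gene"].tolist()
    alteration_calls = call_alterations(
        tables["mutations"], tables["cnv"], tables["expression_z"],
        tables["methylation"], candidates,
        availability=tables["availability"],
        z_threshold=config.z_threshold,
        ndamage_threshold=config.ndamage_threshold,
    )
    write_tsv(alteration_calls, out / "alteration_calls.tsv")
    assessed = tables["availability"].index[
        tables["availability"].any(axis=1)
    ].tolist()
    summary = summarize_samples(alteration_calls, assessed)
    (out / "alteration_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    stages.append("cancer_alterations")

    # 9. enrichment of the planted gene set
    planted = sorted(cancer_truth.planted_genes)
    sres = sscore_set_enrichment(
        tables["annotations"][["gene", "s_score"]], planted,
        threshold=config.s_score_threshold,
        n_perm=config.n_perm, seed=config.seed + 2,
    )
    lres = length_normalized_mutation_enrichment(
        tables["mutations"], tables["annotations"], planted,
        class_filter="lof", n_perm=config.n_perm, seed=config.seed + 3,
    )
    enr = pd.DataFrame([
        {"test": "sscore_set", "observed": sres.observed_stat,
         "p_value": sres.p_value, "n_perm": sres.n_perm},
        {"test": "lof_length_normalized", "observed": lres.observed_stat,
         "p_value": lres.p_value, "n_perm": lres.n_perm},
    ])
    write_tsv(enr, out / "enrichment.tsv")
    stages.append("enrichment")

    manifest = {
        "gisnet_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("screen", "cancer")
        },
        "screen_config": asdict(screen_cfg) if hasattr(screen_cfg, "__dict__") else None,
        "cancer_config": {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in asdict(cancer_cfg).items()
        },
        "optimal_cutoff": c_star,
        "roc_auc": roc_auc(roc),
        "n_gis_genes": len(gis_genes),
        "n_cgis_genes": len(cgis),
        "stages_completed": stages,
        "outputs": {
            p.name: file_checksum(p)
            for p in sorted(out.iterdir())
            if p.name != "manifest.json" and p.is_file()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
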