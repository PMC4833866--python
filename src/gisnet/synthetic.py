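"""Synthetic screen and tumor-cohort generators with known ground truth.

The screen generator emulates a synthetic-genetic-array GCR screen: each
strain (query x bait x assay) has a true GCR rate per cell division, and
each replica-plated patch yields a papillae count from a rare-event model.
GCR events arise during the clonal expansion of the patch, so the number
of independent event lineages is Poisson with mean
``m = rate * cells_per_patch``; since each papilla reflects one event
lineage, the default papillae count is a ``Poisson(m)`` draw (the
``"poisson"`` model). The categorical band boundaries (5/15/150/1000)
then make each one-point score increase correspond to roughly a fivefold
rate increase, matching the empirical score-rate calibration of real
screens. The alternative ``"luria_delbruck"`` model additionally gives
every event lineage a Lea-Coulson jackpot footprint (P(size >= k) = 1/k,
capped at the lawn threshold), for sensitivity analyses in which early
events spread into many papillae.

Query mutations are neutral as single mutants by default
(``fraction_gis_queries = 0``): their biology is expressed through the
planted synergies, like cooperating-GIS-type mutations whose single
deletion leaves the GCR rate at wild type. Baits carry the planted GIS
rate folds.

Double-mutant rates follow a multiplicative null,
``rate = wt_rate * fold_query * fold_bait * synergy_fold``, with
``synergy_fold = 1`` for all pairs except the planted synergies.

The tumor generator plants a set of defective tumor-suppressor-like genes
in a cohort: background mutations accrue per gene proportionally to
protein length, planted genes carry excess loss-of-function mutations,
excess copy-number loss coupled to strongly reduced expression, sporadic
promoter hypermethylation with silencing, and S-scores below -2. Each
sample is profiled on each platform with a configurable availability
probability, mirroring cohorts in which not every sample has every data
type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .interactions import CONTROL_BAIT, WT_QUERY

#: wild-type GCR rates per cell division for the three emulated assays;
#: with the default 2e9 effective cells per patch these give expected
#: event numbers of 0.1, 2 and 10, matching control strain scores of
#: roughly 0.1, ~1 and ~2.7 for the short-repeat, segmental-duplication
#: and Ty-element assays.
DEFAULT_ASSAYS: tuple[tuple[str, float], ...] = (
    ("sGCR", 5e-11),
    ("dGCR", 1e-9),
    ("tyGCR", 5e-9),
)


@dataclass(frozen=True)
class ScreenConfig:
    n_baits: int = 200
    n_queries: int = 10
    assays: Sequence[tuple[str, float]] = DEFAULT_ASSAYS
    fraction_gis: float = 0.15
    fraction_gis_queries: float = 0.0
    gis_fold_mu: float = math.log(5.0)
    gis_fold_sigma: float = 0.5
    fraction_synergy: float = 0.05
    synergy_fold: float = 10.0
    cells_per_patch: float = 2e9
    patches_per_strain: int = 6
    no_growth_prob: float = 0.02
    lawn_threshold: int = 1000
    model: str = "poisson"  # or "luria_delbruck"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_gis", "fraction_gis_queries",
                     "fraction_synergy", "no_growth_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if any(rate <= 0 for _, rate in self.assays):
            raise ValueError("assay wild-type rates must be > 0")
        if self.cells_per_patch <= 0 or self.synergy_fold <= 0:
            raise ValueError("cells_per_patch and synergy_fold must be > 0")
        if self.patches_per_strain < 1:
            raise ValueError("patches_per_strain must be >= 1")
        if self.model not in ("luria_delbruck", "poisson"):
            raise ValueError(f"unknown papillae model: {self.model!r}")


@dataclass(frozen=True)
class ScreenTruth:
    """Planted ground truth of a simulated screen."""

    gene_folds: pd.DataFrame  # gene, rate_fold (shared across assays)
    gis_genes: frozenset[str]
    synergy_pairs: frozenset[tuple[str, str]]  # (query, bait)
    strain_folds: pd.DataFrame  # query, bait, rate_fold of every strain

    def fold_of(self, gene: str) -> float:
        s = self.gene_folds.set_index("gene")["rate_fold"]
        return float(s.get(gene, 1.0))


def _papillae_counts(
    m: np.ndarray, config: ScreenConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw one papillae count per entry of the expected-event array ``m``."""
    if config.model == "poisson":
        return rng.poisson(m)
    n_events = rng.poisson(m)
    total_events = int(n_events.sum())
    counts = np.zeros(m.shape, dtype=np.int64)
    if total_events == 0:
        return counts
    # Lea-Coulson jackpot footprint: P(size >= k) = 1/k, capped at the lawn
    u = rng.random(total_events)
    sizes = np.minimum(np.floor(1.0 / u), config.lawn_threshold + 1).astype(np.int64)
    owner = np.repeat(np.arange(m.size), n_events.ravel())
    flat = np.bincount(owner, weights=sizes, minlength=m.size).astype(np.int64)
    return np.minimum(flat, 10 * config.lawn_threshold).reshape(m.shape)


def simulate_screen(config: ScreenConfig) -> tuple[pd.DataFrame, ScreenTruth]:
    """Simulate a full screen; returns the per-patch table and the truth.

    The patch table has one row per genotype x assay x patch with columns
    ``query_gene``, ``bait_gene``, ``assay``, ``patch_index``,
    ``papillae_count`` and ``grew``. Genotypes comprise the wild-type
    control cross (WT x leu2), bait singles (WT x bait), query singles
    (query x leu2) and every query x bait double mutant.
    """
    rng = np.random.default_rng(config.seed)
    baits = [f"BGN{i:04d}" for i in range(1, config.n_baits + 1)]
    queries = [f"QGN{i:03d}" for i in range(1, config.n_queries + 1)]

    all_genes = baits + queries
    is_gis = np.concatenate([
        rng.random(config.n_baits) < config.fraction_gis,
        rng.random(config.n_queries) < config.fraction_gis_queries,
    ])
    folds = np.ones(len(all_genes))
    folds[is_gis] = rng.lognormal(
        config.gis_fold_mu, config.gis_fold_sigma, int(is_gis.sum())
    )
    fold_of = dict(zip(all_genes, folds))
    gis_genes = frozenset(g for g, flag in zip(all_genes, is_gis) if flag)

    pair_mask = rng.random((config.n_queries, config.n_baits)) < config.fraction_synergy
    synergy_pairs = frozenset(
        (queries[qi], baits[bi]) for qi, bi in zip(*np.nonzero(pair_mask))
    )

    genotypes: list[tuple[str, str, float]] = [(WT_QUERY, CONTROL_BAIT, 1.0)]
    genotypes += [(WT_QUERY, b, fold_of[b]) for b in baits]
    genotypes += [(q, CONTROL_BAIT, fold_of[q]) for q in queries]
    for qi, q in enumerate(queries):
        for bi, b in enumerate(baits):
            syn = config.synergy_fold if pair_mask[qi, bi] else 1.0
            genotypes.append((q, b, fold_of[q] * fold_of[b] * syn))

    n_strain = len(genotypes)
    strain_folds = np.array([f for _, _, f in genotypes])
    frames = []
    for assay, wt_rate in config.assays:
        rates = wt_rate * strain_folds
        m = np.broadcast_to(
            (rates * config.cells_per_patch)[:, None],
            (n_strain, config.patches_per_strain),
        )
        # strain-level cross failures: every patch of a failed strain
        failed = rng.random(n_strain) < config.no_growth_prob
        counts = _papillae_counts(np.ascontiguousarray(m), config, rng)
        counts[failed, :] = 0
        grew = np.broadcast_to(~failed[:, None], counts.shape)
        frames.append(pd.DataFrame({
            "query_gene": np.repeat([q for q, _, _ in genotypes], config.patches_per_strain),
            "bait_gene": np.repeat([b for _, b, _ in genotypes], config.patches_per_strain),
            "assay": assay,
            "patch_index": np.tile(
                np.arange(1, config.patches_per_strain + 1), n_strain
            ),
            "papillae_count": counts.ravel(),
            "grew": grew.ravel(),
        }))
    patches = pd.concat(frames, ignore_index=True)
    truth = ScreenTruth(
        gene_folds=pd.DataFrame({"gene": all_genes, "rate_fold": folds}),
        gis_genes=gis_genes,
        synergy_pairs=synergy_pairs,
        strain_folds=pd.DataFrame(
            genotypes, columns=["query", "bait", "rate_fold"]
        ),
    )
    return patches, truth


# ---------------------------------------------------------------------------
# tumor cohorts


@dataclass(frozen=True)
class CancerConfig:
    n_samples: int = 500
    n_genes: int = 1000
    planted_ts_genes: int = 20
    length_log_mean: float = math.log(500.0)
    length_log_sigma: float = 0.6
    background_mut_rate: float = 4e-6  # mutations per amino acid per sample
    planted_lof_rate: float = 0.05  # extra LOF mutations per planted gene/sample
    cnv_loss_prob: float = 0.02
    homdel_prob: float = 0.002
    planted_cnv_loss_prob: float = 0.15
    planted_homdel_prob: float = 0.02
    expr_shift_on_loss: float = -3.0
    silencing_prob: float = 0.02  # planted genes; background is 10x rarer
    missense_ndamage_probs: Sequence[float] = (
        0.22, 0.20, 0.16, 0.14, 0.10, 0.10, 0.08,
    )
    availability_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "mutation": 0.95,
            "cnv": 0.95,
            "expression": 0.90,
            "methylation": 0.85,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.planted_lof_rate, self.cnv_loss_prob, self.homdel_prob,
            self.planted_cnv_loss_prob, self.planted_homdel_prob,
            self.silencing_prob, *self.availability_probs.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.planted_ts_genes > self.n_genes:
            raise ValueError("planted_ts_genes cannot exceed n_genes")
        if self.background_mut_rate < 0:
            raise ValueError("background_mut_rate must be >= 0")
        if abs(sum(self.missense_ndamage_probs) - 1.0) > 1e-9:
            raise ValueError("missense_ndamage_probs must sum to 1")


_BACKGROUND_CLASSES = np.array([
    "missense", "silent", "nonsense", "frameshift_insertion",
    "frameshift_deletion", "inframe_insertion", "inframe_deletion",
    "splice_site", "other",
])
_BACKGROUND_CLASS_PROBS = np.array(
    [0.58, 0.25, 0.04, 0.02, 0.03, 0.01, 0.01, 0.02, 0.04]
)
_LOF_CLASSES_ARR = np.array([
    "nonsense", "frameshift_insertion", "frameshift_deletion",
    "inframe_insertion", "inframe_deletion", "splice_site",
])
_LOF_CLASS_PROBS = np.array([0.30, 0.15, 0.25, 0.05, 0.05, 0.20])


@dataclass(frozen=True)
class CancerTruth:
    planted_genes: frozenset[str]


def simulate_cancer(config: CancerConfig) -> tuple[dict[str, pd.DataFrame], CancerTruth]:
    """Simulate a tumor cohort; returns the data tables and the truth.

    The returned dict holds ``mutations``, ``cnv``, ``expression_z``,
    ``methylation``, ``annotations`` (gene, length_aa, s_score) and
    ``availability`` (samples x platforms booleans). Matrices carry NaN
    for samples not profiled on a platform.
    """
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"HGN{i:04d}" for i in range(1, config.n_genes + 1)])
    samples = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]
    planted = frozenset(
        genes[rng.choice(config.n_genes, config.planted_ts_genes, replace=False)]
    )
    planted_mask = np.isin(genes, list(planted))

    lengths = np.maximum(
        1, np.round(rng.lognormal(config.length_log_mean, config.length_log_sigma,
                                  config.n_genes))
    ).astype(int)

    s_scores = rng.normal(0.0, 1.0, config.n_genes)
    s_scores[planted_mask] = -2.0 - np.abs(
        rng.normal(1.0, 0.5, int(planted_mask.sum()))
    )
    annotations = pd.DataFrame(
        {"gene": genes, "length_aa": lengths, "s_score": s_scores}
    )

    avail = pd.DataFrame(
        {
            platform: rng.random(config.n_samples) < p
            for platform, p in config.availability_probs.items()
        },
        index=samples,
    )

    # --- mutations: background Poisson(length * rate) per sample x gene,
    # plus planted LOF excess in planted genes
    lam = lengths * config.background_mut_rate
    mut_samples = np.array([s for s in samples if avail.at[s, "mutation"]])
    bg_counts = rng.poisson(np.tile(lam, (len(mut_samples), 1)))
    si, gi = np.nonzero(bg_counts)
    reps = bg_counts[si, gi]
    bg_sample = np.repeat(mut_samples[si], reps)
    bg_gene = np.repeat(genes[gi], reps)
    n_bg = int(reps.sum())
    bg_class = rng.choice(_BACKGROUND_CLASSES, size=n_bg, p=_BACKGROUND_CLASS_PROBS)
    bg_ndamage = np.full(n_bg, np.nan)
    is_mis = bg_class == "missense"
    bg_ndamage[is_mis] = rng.choice(
        7, size=int(is_mis.sum()), p=np.asarray(config.missense_ndamage_probs)
    )
    is_fs = np.char.startswith(bg_class.astype(str), "frameshift")
    bg_mono = is_fs & (rng.random(n_bg) < 0.3)

    planted_idx = np.nonzero(planted_mask)[0]
    extra = rng.random((len(mut_samples), len(planted_idx))) < config.planted_lof_rate
    esi, epi = np.nonzero(extra)
    n_extra = len(esi)
    ex_class = rng.choice(_LOF_CLASSES_ARR, size=n_extra, p=_LOF_CLASS_PROBS)
    ex_fs = np.char.startswith(ex_class.astype(str), "frameshift")
    ex_mono = ex_fs & (rng.random(n_extra) < 0.3)
    mutations = pd.DataFrame({
        "sample": np.concatenate([bg_sample, mut_samples[esi]]),
        "gene": np.concatenate([bg_gene, genes[planted_idx[epi]]]),
        "variant_class": np.concatenate([bg_class, ex_class]),
        "ndamage": np.concatenate([bg_ndamage, np.full(n_extra, np.nan)]),
        "in_mononucleotide_repeat": np.concatenate([bg_mono, ex_mono]),
    })

    # --- copy number (GISTIC-style thresholded integers)
    loss_p = np.where(planted_mask, config.planted_cnv_loss_prob, config.cnv_loss_prob)
    homdel_p = np.where(planted_mask, config.planted_homdel_prob, config.homdel_prob)
    u = rng.random((config.n_samples, config.n_genes))
    cn = np.zeros((config.n_samples, config.n_genes), dtype=float)
    cn[u < loss_p] = -1
    cn[u < homdel_p] = -2
    gains = rng.random((config.n_samples, config.n_genes))
    cn[(cn == 0) & (gains < 0.02)] = 1
    cn[(cn == 0) & (gains < 0.004)] = 2

    # --- expression Z, coupled to copy loss; silencing adds methylation
    z = rng.normal(0.0, 1.0, (config.n_samples, config.n_genes))
    z[cn < 0] += config.expr_shift_on_loss * np.where(cn[cn < 0] == -2, 1.4, 1.0)

    sil_p = np.where(planted_mask, config.silencing_prob, config.silencing_prob / 10.0)
    silenced = (rng.random((config.n_samples, config.n_genes)) < sil_p) & (cn == 0)
    z[silenced] += config.expr_shift_on_loss
    meth = silenced | (rng.random((config.n_samples, config.n_genes)) < 0.01)

    cnv = pd.DataFrame(cn, index=samples, columns=genes)
    expr = pd.DataFrame(z, index=samples, columns=genes)
    methylation = pd.DataFrame(meth, index=samples, columns=genes)
    cnv.loc[~avail["cnv"].to_numpy(), :] = np.nan
    expr.loc[~avail["expression"].to_numpy(), :] = np.nan
    methylation = methylation.astype(float)
    methylation.loc[~avail["methylation"].to_numpy(), :] = np.nan

    tables = {
        "mutations": mutations,
        "cnv": cnv,
        "expression_z": expr,
        "methylation": methylation,
        "annotations": annotations,
        "availability": avail,
    }
    return tables, CancerTruth(planted_genes=planted)
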