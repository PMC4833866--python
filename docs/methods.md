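# Methods

`gisnet` reimplements, as a tested library, the analytical pipeline of a
semi-quantitative gross-chromosomal-rearrangement (GCR) screen in
*Saccharomyces cerevisiae* and the downstream analysis of
Genome-Instability-Suppressing (GIS) gene defects in tumor cohorts. This
note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Patch scoring

A patch test grows a patch of cells from one spore clone and
replica-plates it onto double-selective media (canavanine + 5-FOA);
papillae are colonies founded by independent GCR event lineages. Each
patch receives a categorical score from its papillae count:

| score | papillae |
|---|---|
| 0 | none |
| 1 | 1–5 |
| 2 | 6–15 |
| 3 | 16–150 (countable) |
| 4 | 151–1,000 (too many/too close to count) |
| 5 | confluent lawn (> 1,000) |

The upper boundaries of the two open-ended bands are fixed at 150 and
1,000 for determinism (the countable band is only loosely bounded in
practice at roughly 150–200); both are configurable. The *GCR strain
score* is the arithmetic mean of all valid patch scores of one genotype in
one assay — all available patches are averaged, not a fixed three, with a
warning below 3 replicates. Patches that failed to grow carry a
`NO_GROWTH` sentinel rather than a numeric code so they can never leak
into an average; a strain whose patches all failed has an undefined score
and is flagged for exclusion.

Because the band boundaries grow roughly fivefold per score point, a
one-point score increase corresponds to roughly a fivefold increase in
the underlying GCR rate under the event-count model below; this matches
the empirical score–rate calibration reported for real screens.

## Cutoff optimization and the discrete KS test

Given pairs (rate fold over wild type, strain score), the positive class
is rate fold ≥ 3. For a cutoff `c`, `SENS = TP/(TP+FN)` and
`SPEC = TN/(TN+FP)` with a single call rule — call positive iff score ≥
`c` — so the four cells partition the data (descriptions of the
false-positive cell sometimes use a strict inequality; a mixed rule would
not partition). The optimal cutoff maximizes `w1·SENS + w2·SPEC` over a
candidate grid of midpoints between consecutive distinct observed scores
plus sentinels below the minimum and above the maximum; ties in cost break
toward the lowest cutoff, favouring sensitivity, consistent with the
default weighting `w1 = 2, w2 = 1` (false negatives are lost; false
positives can be removed by follow-up fluctuation assays). ROC curves and
trapezoidal AUC are computed over the same grid.

Patch-score distributions are compared with a two-sample
Kolmogorov–Smirnov test on the discrete support {0..5}. Because the
support is discrete, the asymptotic KS null is wrong; the null is instead
generated by Monte-Carlo permutation of the pooled sample (the cited
discrete-KS methodology offers several null constructions and permutation
is the assumption-free one for the two-sample case). The p-value uses the
add-one rank convention `(#{D_perm ≥ D_obs} + 1)/(n_mc + 1)` and is never
zero. Ties between permuted and observed D count as "as extreme", which
makes the test conservative, never anticonservative.

## GIS and cGIS calling

Per assay, a gene suppresses GCRs when its single-mutant strain score is
at least `delta = 0.4` above the wild-type control score for that assay
(the control strain's measured score is the reference, per assay, rather
than a common rounded baseline — the control scores differ strongly
between assays). Measured rate folds override scores in both directions:
fold < 3 removes a score-flagged gene; fold ≥ 3 flags a gene regardless
of score. Previously published suppressor genes enter through an explicit
prior list with their own evidence tag; no curation logic is implemented.
Assay-overlap counts (Venn cells) are exact subset tallies. Screen
completeness extrapolates hits in a random sample of untested deletion
strains: `missed = (pool − tested) × hits/screened`.

A query × bait double mutant is called interacting when its score exceeds
the higher of the two single-mutant scores by ≥ `delta = 0.4`. Singles
come from the wild-type-query cross (baits) and the control-bait cross
(queries); an undefined single makes the pair untestable. Scores at or
above 4.5 are flagged as near assay saturation (strains scoring ~4 as
singles leave little headroom for a 0.4 differential) but calls are
retained. Reciprocal (a×b, b×a) measurements are summarized by mean
absolute score difference and call agreement; disagreeing reciprocal calls
are both reported, never averaged. cGIS genes are interacting baits minus
the GIS list. Modules (complexes/pathways, GMT input) are group 1 when at
least two mutated members have called interactions and some query is
shared by two or more of them, otherwise group 2; the "shared by at least
two members" reading is used rather than requiring a common query across
*all* interacting members, which matters only for modules with ≥ 3
interacting members. An optional rate-based confirmation classifies a
double as synergistic when its rate fold exceeds the *sum* of the single
folds (additive null, default) or their product (multiplicative null) —
the field's notion of "synergistic increase" is not standardized, so both
are exposed.

## Tumor-cohort alteration classification

Candidate tumor-suppressor homologs are selected by S-score (a
precomputed integrated copy-number/expression/methylation/mutation
signature): s ≤ −2 (strict) plus a borderline band (−2, −1.95] reported
separately; proto-oncogene-like scores (≥ 2) are selected by the mirrored
rule but carried no further. Per sample × gene, four defect categories:

* **lof_mutation** — nonsense, frameshift ins/del, in-frame ins/del or
  splice-site variant;
* **deleterious_missense** — missense with Ndamage ≥ 5 of 6 predictor
  calls (predictor outputs are inputs, not recomputed);
* **cn_reduced_low_expression** — GISTIC call −1 or −2 with expression
  Z < −2;
* **silenced** — hypermethylation flag with Z < −2 and GISTIC ≥ 0. The
  no-copy-loss condition is this package's fixed reading of "apparent
  silencing": it isolates epigenetic loss from copy-number-driven loss;
  all three thresholds are configurable.

Platforms a sample was not profiled on leave categories unassessed, not
negative; samples with no platform at all are excluded from denominators.
The combined summary partitions samples into mutually exclusive
combinations of mutation / CN-with-low-expression / silencing, separately
for the LOF-only and LOF-plus-deleterious-missense mutation definitions,
over all samples with any data (the denominator choice is configurable
because cohort summaries can alternatively be restricted to
fully-profiled samples). An exclusion list lets mismatch-repair-defective
cases be dropped before summarization; hypermutator detection itself is
out of scope.

## Randomization tests

Both enrichment tests report the add-one rank p
`(#{perm ≥ obs} + 1)/(n_perm + 1)` with `n_perm = 10,000` by default,
one-sided for enrichment.

* **S-score set enrichment**: observed = number of query genes with
  extreme scores; null sets are uniform same-size draws without
  replacement from the scored pool.
* **Length-normalized mutation enrichment**: observed = qualifying
  mutations in the query set; null sets accumulate random genes without
  replacement until the cumulative protein length (amino acids of the
  longest coding region) reaches the query set's total. The last gene may
  overshoot; no rescaling is applied and the mean overshoot fraction is
  reported. The overshoot makes the test slightly conservative, by an
  amount that scales as one gene's length over the set's total — for sets
  of hundreds of genes it is negligible. Per-class presets cover
  deletions, insertions, frameshift subsets, nonsense, splice-site and
  mononucleotide-repeat frameshifts (via the repeat flag carried on
  mutation records).

A same-size (length-naive) permutation variant is exposed for comparison
only: with mutation burdens proportional to coding length it is strongly
anticonservative for long-gene sets, which is the bias the normalization
exists to remove.

## Synthetic data generators

The screen generator defines the study conditions for everything
upstream of real data. Each strain has a true GCR rate: wild-type assay
rate × bait fold × query fold × synergy fold. Planted GIS baits
(default fraction 0.15, matching the enrichment of a candidate-based bait
collection) draw folds from lognormal(ln 5, 0.5) — median fivefold, the
scale of typical single-mutant effects detectable by patch tests. Query
mutations are neutral as singles by default (`fraction_gis_queries = 0`),
like cooperating-type mutations whose effect appears only in combination;
planted synergies (default 5% of pairs) multiply the multiplicative null
by `synergy_fold = 10`. Three assays are emulated with wild-type rates
5e-11, 1e-9 and 5e-9 per cell division; with the default 2×10⁹ effective
cells per patch these give expected event numbers 0.1, 2 and 10 and
control strain scores of roughly 0.1, 0.9 and 2.0–2.7, bracketing real
control behaviour across assay types.

Papillae counts: the number of independent GCR event lineages in a patch
is Poisson with mean `m = rate × cells_per_patch`, and since each papilla
reflects one event lineage the default count model is `Poisson(m)`. An
alternative `luria_delbruck` model additionally gives each lineage a
Lea–Coulson jackpot footprint (P(size ≥ k) = 1/k, capped at the lawn
threshold of 1,000), for sensitivity analyses where early events spread
into many papillae; under that model strain scores are markedly
heavier-tailed and interaction calling degrades, which is itself a useful
robustness probe. Cross failures are strain-level: with probability
`no_growth_prob` every patch of a strain is flagged not-grown.

The tumor generator plants a set of defective genes in a cohort:
background mutations per gene are Poisson(length × rate) — doubling a
gene's length doubles its expected background burden — while planted
genes receive extra LOF mutations (default 0.05 per sample), elevated
copy-number loss (0.15 vs 0.02 background) and homozygous deletion,
expression Z shifted by −3 (−4.2 for homozygous deletions) when copy
number is reduced, sporadic promoter hypermethylation with silencing-level
expression loss, and S-scores below −2. Non-planted genes have standard
normal S-scores. Per-platform availability flags (mutation 0.95, CNV
0.95, expression 0.90, methylation 0.85) emulate cohorts where not every
sample has every data type.

What the generators do *not* emulate: breakpoint sequences and GCR
mechanisms; SGA mating/selection artifacts beyond whole-strain failure;
correlated platform dropout; hypermutator samples; subclonality and
purity; gene–gene correlation in copy-number segments (each gene is
independent, whereas real GISTIC calls are segmental). Passing tests
therefore demonstrate correctness of the calling rules and calibration of
the statistics under these idealized conditions, not robustness to those
real-data complications.

## Numerical choices and problem sizes

Monte-Carlo p-values always use the add-one convention and a seeded
`numpy.random.Generator`; fixing the seed fixes every output byte, and
permutations are generated in memory-bounded chunks. Degenerate inputs
fail loudly: empty patch lists, missing wild-type control scores,
one-class cutoff data, empty samples and empty class filters raise
`ValueError`.

The test suite exercises calibration at desk scale: 1,000 null trials for
the discrete KS test (samples of 100, 199 permutations) and for each
enrichment test (pools of 500–1,000 genes, sets of 100, 199–999
permutations — set sizes chosen so the discrete statistic's support is
wide and the length-matched overshoot is negligible, the regime in which
the tests are actually used); 500 cohorts for the length-bias
discrimination experiment; and a 10-query × 200-bait screen with 6
patches per strain for parameter recovery. These sizes were chosen to
make the Monte-Carlo error small relative to the asserted tolerances.

## Known limitations

* The interaction truth in simulations is "beyond-multiplicative" only;
  a double mutant of two strong suppressors on the multiplicative null is
  genuinely greater-than-additive and would be called by the differential
  rule, so simulated precision against that truth is meaningful only when
  query single-mutant effects are neutral (the default).
* The score–rate calibration (one point ≈ fivefold) is a property of the
  band boundaries and the event-count model; no invariant asserts it for
  the jackpot model or for real data.
* The discrete KS permutation null conditions on the pooled sample; very
  small samples give coarse p-value granularity.
* S-scores, missense-predictor calls and GISTIC calls are consumed as
  inputs; their provenance and quality are outside the package.
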