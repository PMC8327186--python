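# Methods

`regdiscord` screens case/control single-cell RNA-seq for transcription
factors (TFs) that physically partner with a perturbed TF. The signature it
looks for is *discordance*: a TF's regulon (its predicted target-gene set)
loses activity in knockout cells while the TF's own expression does not
change. A TF whose regulon collapses *and* whose expression drops is more
parsimoniously a downstream target of the perturbed factor; a TF whose
regulon collapses while its expression is untouched needs another
explanation, and a lost protein–protein interaction with the perturbed TF is
the natural candidate. The pipeline automates that argument end to end:
quality control, clustering and cell-type annotation, selection of a focal
population, hurdle-model differential expression, co-expression regulon
inference, per-cell regulon-activity scoring, binarized differential
activity, and the final discordance classification.

## Quality control

Cells are kept when they show 1000–5000 detected genes and 1800–10,000 UMIs
(both ranges inclusive) and strictly less than 6% mitochondrial counts.
Cells whose blood-marker (hemoglobin) count fraction exceeds a configurable
threshold (default 1%; no canonical value exists for this judgement call,
so it is exposed in the config) are flagged as contaminated background and
removed. Samples are kept only with strictly more than 500 surviving cells;
a manual sample-exclusion list supports study-specific removals (e.g. a
control animal with anomalous expression of the perturbed gene). Genes must
be detected in at least 3 retained cells. An optional strict UMI cap
(<4000) reproduces a depth-matched sensitivity re-analysis and is off by
default. The composed filter (cells → background → samples → genes) is a
fixed point: re-running it on its own output removes nothing.

## Clustering, annotation, focal population

Expression is depth-normalized to counts-per-10k and log2-transformed.
The 2000 most variable genes are chosen by binned dispersion
(variance/mean, z-scored within 20 equal-occupancy mean bins; ties break on
gene identifier). Cells are embedded with PCA (20 components) on z-scaled
HVGs, connected in a cosine k-nearest-neighbour graph (k = 20), and
partitioned by greedy modularity optimization — a deterministic stand-in
for the usual Louvain/Leiden step, chosen because its result depends only
on the graph. Each cluster is annotated as the cell type whose marker
panel has the highest mean z-score across the cluster's cells; an exact tie
leaves the cluster unassigned rather than guessing. The focal population is
the cells of the eligible neuronal types (intermediate progenitors, newborn
neurons, deep and upper layer) with a strictly positive raw count of the
focal gene (*Satb2* by default), mirroring the projection-neuron subset in
which the original screen was performed.

## Hurdle differential expression

Each gene is tested between genotypes with a two-part hurdle model in the
MAST tradition: a logistic regression of detection (count > 0) and a
Gaussian regression of log2(1 + CP10K) on detected cells, both with an
intercept, a genotype indicator, and the cellular detection rate (CDR,
standardized log total UMIs) as a confounder. The test statistic sums the
two components' likelihood-ratio statistics for dropping genotype, with one
degree of freedom per non-degenerate component, referred to a chi-square
distribution. A component is degenerate when detection is constant or
fewer than 3 cells are detected; both degenerate gives p = 1. Perfect
separation in the logistic part is handled by probability clamping at
[1e-8, 1 − 1e-8] with damped Newton steps, never an exception. The
continuous part uses plain maximum likelihood — MAST's empirical-Bayes
variance shrinkage is intentionally omitted because its constants are tool
version dependent; instead, calibration is demonstrated by simulation: on a
null design with genotype-correlated library sizes the rejection rate at
α = 0.05 stays near nominal with the CDR covariate and inflates drastically
without it. log2 fold change is the difference in mean log2(1 + CP10K)
over all focal cells (zeros included), a single sign-symmetric definition
independent of the test. Genes are called DE at BH FDR < 0.05 and
|log2FC| > 0.25; both knobs are configurable.

Note one consequence of the CP10K scale: when a knockout suppresses a
sizable slice of the transcriptome, depth normalization slightly inflates
every unchanged gene's CP10K in knockout cells. The fold-change gate
absorbs this compositional shift; it is visible in the synthetic data as a
small positive log2FC bias for unaffected genes.

## Regulon inference

When no regulon file (GMT) is supplied, co-expression regulons are inferred
GENIE3-style: for each target gene, an ensemble of extremely randomized
regression trees predicts its normalized expression from all TF
expressions, and each TF records its mean unnormalized impurity-reduction
importance (targets are standardized to unit variance first, which makes
importances comparable across targets). Self-edges are masked. The
ensembles are regularized (25 trees, depth ≤ 8, minimum leaf size 20,
~1/3 of TFs as split candidates, 90% bootstrap samples, at most 500 cells)
— settings chosen for stable rankings at interactive runtimes; all are
configurable. Two pipeline-level choices matter:

- **Reference-genotype inference.** The network is inferred on control
  (WT) focal cells only, then scored on all focal cells. Inferring on the
  mixture lets the perturbation itself masquerade as co-expression: any TF
  whose expression differs between genotypes (e.g. a decoy that *is*
  differentially expressed) becomes a spurious predictor of every
  suppressed gene. Control-only inference removes that confound.
- **Importance-share pruning.** A TF keeps a target only if it holds at
  least 15% of the target's total importance across all TFs
  (`grn_min_target_share`), then takes its top 50 targets. This is the
  package's surrogate for SCENIC's motif-based pruning (out of scope here,
  as it requires external motif databases): without it, regulons accumulate
  weakly attributed genes — typically highly expressed housekeeping-like
  genes that every TF "predicts" a little through residual library and
  compositional covariation — and those genes carry systematic rank
  artifacts into the activity scores.

## Regulon activity, binarization, differential activity

Per-cell activity of a regulon is the area under its recovery curve: genes
are ranked within each cell by descending raw count (ties broken by a
seeded deterministic hash of cell and gene identifiers, so the whole
pipeline is bit-reproducible and independent of storage order); with
k = ⌈0.05 × G⌉, the curve counts regulon targets among the top-i ranked
genes for i = 1..k and the AUC is the curve's sum normalized by its maximum
attainable value. Raw counts feed the ranking (within-cell ranks are
invariant to depth normalization, so the choice is cosmetic). Each
regulon is binarized at its mean AUC across cells, strictly above the mean
meaning "high activity" — a constant-activity regulon is therefore low
everywhere. Differential activity between genotypes is a two-sided Fisher
exact test on the per-regulon 2×2 genotype × state table with BH
correction; regulons are categorized WT-active (δ = active fraction WT −
KO ≥ 0.3 at FDR < 0.05), KO-active (symmetric), or non-differential. The
quantitative rule replaces the original by-eye triage of binarized heatmaps
with an auditable surrogate; both knobs are exposed. Cells are re-clustered
on their binary activity profiles (Jaccard-distance kNN graph, ties broken
by cell identifier) and genotype partitioning is quantified as neighbor
purity: the mean fraction of each cell's graph neighbors sharing its
genotype (1 = perfect separation, 0.5 = chance for balanced classes).

## Interactor calls

A regulon head passes when (i) its regulon is differentially active,
(ii) the head itself is *not* differentially expressed (the discordance
criterion; "not DE" is the exact negation of the DEG call), (iii) the head
is detected in at least one quarter of focal cells (inclusive), and
(iv) optionally, the head belongs to a configured functional gene set
(e.g. a neurogenesis/neuron-differentiation panel supplied as GMT; no live
ontology queries). The bHLH-versus-other family split and the DE fraction
among differentially active heads are reported as percentages but not used
as filters by default, since family membership is interpretation rather
than selection; an `exclude_families` option exists. Every failure records
its reasons, so the table documents why each head was rejected. Finally,
the DEG list is intersected with any passing partner's regulon targets to
produce candidate co-regulated ("common target") gene lists.

## Synthetic data generator

No public accession exists for the motivating dataset, so the generator is
a first-class module that emulates its design: 2 genotypes × 3 samples ×
~800 cells, 2500 genes, 8 marker-defined cell types (one focal
*Satb2*-like upper-layer population plus the other eligible neuronal
types), negative-binomial counts via gamma–Poisson mixing with log-normal
per-cell library factors, knockout libraries systematically shallower
(factor 0.85), ~2% hemoglobin-contaminated cells, ~4% deliberately
QC-violating cells, and planted truth: 5 partner TFs whose 30-gene regulons
are multiplicatively suppressed (f = 0.4) in knockout cells of the eligible
types while the TF itself is untouched; 3 decoy TFs that are themselves
differentially expressed with their regulons following them down; and 40
directly perturbed DEGs (2-fold up or down).

Structural choices worth knowing when interpreting test results:

- **Expression tiers.** Genes fall into a high "housekeeping" tier (80
  genes, log-normal means around 8), a mid "buffer" tier (150 genes, mean
  3.5), and a low background (mean ~1). Rank-based activity scoring only carries signal if
  the top-of-ranking is contested: the high tier provides stable
  competition in both genotypes, and the buffer absorbs the top-list slots
  freed when suppressed targets drop out of knockout rankings — without it,
  those slots are claimed quasi-randomly by low-expressed genes and every
  low-expression gene set acquires a spurious knockout-biased activity.
- **Program structure.** Each planted TF's regulon fires as an on/off
  program per cell (on with probability 0.6, identically in both
  genotypes); "on" multiplies target means to ~4.5 and the TF itself to its
  active level. This is what makes co-expression inference possible (target
  and TF covary across cells) while keeping binarized activity crisp.
  Non-planted TFs couple to their targets through a weaker log-normal
  latent instead, giving the inference stage realistic distractors.
- **Mean–dispersion trend.** NB dispersion decays from 0.5 at low means to
  0.15 for highly expressed genes, as in real UMI data; constant high
  dispersion would blur the rank competition that activity scoring relies
  on.

What the generator does *not* emulate: ambient RNA, doublets, batch
chemistry, gene-length effects, or transcriptional bursting beyond the NB.
Passing tests therefore demonstrate the pipeline's internal logic and its
behavior under a faithful but idealized mechanism — not performance on any
real dataset.

The null scenario (f = 1, no decoys, no planted DEGs, equal library-size
distributions) is the control condition: the pipeline run on it should find
chance-level genotype purity and no passing interactor calls.

## Numerical and reproducibility choices

All randomness flows from a single integer seed: the generator, the
tie-break hash in ranking, tree-ensemble seeds (derived per target gene
from a hash of the gene identifier, so importances are invariant to gene
order), PCA initialization, and cell subsampling. Two runs with the same
inputs, config and seed produce byte-identical report tables. Ties are
broken deterministically everywhere (gene or cell identifier, or seeded
hash), never by array position. Report tables are sorted by FDR then
identifier. Problem sizes used by the test-suite simulations — 500 genes ×
600 cells for calibration and power, the default scenario for the
end-to-end recovery checks, a half-size scenario for determinism — were
chosen to give stable verdicts at interactive runtimes.

## Known limitations

- Co-expression regulons without motif pruning conflate direct and
  indirect regulation; the importance-share filter removes promiscuous
  edges but cannot recover motif-level specificity.
- The discordance criterion cannot distinguish a lost physical interaction
  from other post-transcriptional mechanisms (localization, degradation,
  competition for a cofactor); it nominates candidates for biochemical
  validation, nothing more.
- The mean-threshold binarization assumes a roughly bimodal activity
  distribution; for regulons active in a small cell fraction the mean sits
  near the inactive mode and the high state becomes noisy.
- Neighbor purity depends on class balance; it is reported alongside the
  focal-population genotype counts for that reason.
- With ~2500 genes the top-5% recovery window is ~125 ranks; regulon AUC
  values are therefore small in absolute terms and only their thresholded
  states are interpreted.
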