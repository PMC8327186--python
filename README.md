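# regdiscord

Predict cell-type-specific interaction partners of a perturbed
transcription factor (TF) from case/control single-cell RNA-seq.

## The problem

Knocking out a broadly expressed TF (an E-protein such as TCF4, say)
dysregulates far more genes than the factor binds directly, because much of
its work happens in complexes with other regulators. Co-immunoprecipitation
can test a candidate partner, but first you need candidates. This package
implements a computational screen for them: if TF *R* partners with the
perturbed factor, then in knockout (KO) cells the joint complex is gone, so
the genes *R* regulates — its **regulon** — lose expression even though *R*
itself is still transcribed normally. The screen therefore looks for
regulons whose **activity collapses in KO cells while the regulon head's
own expression is unchanged** (the *discordance criterion*), and rejects
heads that are themselves differentially expressed as probable downstream
targets rather than partners.

## The method

Given a genes × cells UMI count matrix with WT/KO labels, the pipeline:

1. **QC** — keep cells with 1000–5000 genes, 1800–10,000 UMIs, <6%
   mitochondrial counts; drop hemoglobin-contaminated cells; keep samples
   with >500 cells; keep genes detected in ≥3 cells.
2. **Cluster & annotate** — log2 CP10K, top-2000 HVGs, PCA, cosine kNN
   graph, greedy modularity communities, marker-score cell typing; select
   the focal population (eligible neuronal types with *Satb2* count > 0).
3. **Differential expression** — MAST-style two-part hurdle test per gene
   (logistic detection + Gaussian expression, both adjusted for the
   cellular detection rate), BH-corrected; DEGs at FDR < 0.05 and
   |log2FC| > 0.25.
4. **Regulons** — GENIE3-style tree-ensemble importances (TF → target) on
   control cells, importance-share pruning, top-50 targets per TF; or
   user-supplied GMT regulons.
5. **Activity** — per-cell recovery-curve AUC per regulon
   (AUCell-style, top 5% of the within-cell ranking), binarized at the
   per-regulon mean; Fisher exact test on the genotype × state table sorts
   regulons into WT-active / non-differential / KO-active; cells are
   re-clustered on binary activity profiles and genotype partitioning is
   quantified as neighbor purity.
6. **Interactor calls** — a regulon head passes when it is differentially
   active, *not* differentially expressed, and detected in ≥¼ of focal
   cells (plus an optional functional-gene-set filter); the DEG list is
   intersected with each passing partner's targets to give common-target
   lists. The bHLH-vs-other and DE-vs-not tallies are reported.

A seeded synthetic-data module generates the full study design — two
genotypes × three samples, ~800 cells each, 15 cell types' worth of
structure collapsed to 8 marker-defined types, planted partner TFs, decoy
DE TFs and direct DEGs — so every stage is testable without any download.
See `docs/methods.md` for the model and the design decisions.

## Worked example

```
regdiscord simulate --out data/ --seed 1
regdiscord run --data data/ --out results/ --seed 1
```

which ends with (numbers from this exact invocation):

```
regdiscord run summary (results)
  DEGs: 285 (22 up, 263 down in KO)
  regulon categories: WT_ACTIVE=8, NON_DIFFERENTIAL=26, KO_ACTIVE=0
  differentially active heads: 8 (bHLH 0.00%, regulator-DE 37.50%)
  passing interactor candidates: 5 (Tf00, Tf01, Tf02, Tf03, Tf04)
  common DEG/regulon targets listed: 149
  genotype neighbor purity: 0.946
```

Reading it: 34 regulons survive inference (TFs with only weakly attributed
targets yield none), and 8 of them lose activity in the KO (`WT_ACTIVE`). Three of those heads (37.5%) are themselves differentially
expressed — the planted decoys — and are rejected with the reason
`regulator differentially expressed`. The five that pass are exactly the
planted partner TFs (`Tf00`–`Tf04`). The KO's suppressed regulon targets
dominate the DEG list (hence 259 down), the common-target lists collect
the DEGs inside each partner's regulon, and a neighbor purity of 0.95 on
binarized activity profiles reproduces the near-complete genotype
partitioning the screen predicts. On the null scenario
(`--scenario null`) purity sits at chance and no candidate passes.

The same pipeline runs on real 10x-style data: point `--data` at a
directory with `matrix.mtx`, `features.tsv`, `barcodes.tsv`, a `cells.tsv`
(cell_id, sample_id, genotype) and a `genes.tsv` (gene_id, symbol, is_mito,
is_tf, tf_family, is_blood_marker, functional_sets), plus a `markers.tsv`
mapping cell types to marker genes; thresholds live in a flat
`key=value`/YAML config (`--config`).

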