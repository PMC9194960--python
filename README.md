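# irlnc

Immune-related lncRNA discovery from paired lncRNA/mRNA expression profiles,
with subtype discovery and per-sample immune characterization. The pipeline
re-implements, as tested reusable Python, an integrated analysis for inflamed
vs. normal dental-pulp cohorts:

1. **Differential expression** (`irlnc.de`) — two-group moderated
   t-statistics with empirical-Bayes variance shrinkage (log-F moment
   matching, digamma/trigamma inversion), Benjamini–Hochberg FDR.
2. **lncRES scoring** (`irlnc.lncres`) — the core algorithm: for each lncRNA
   all mRNAs are ranked by `rs = -log10(p) * sign(cc)` from pairwise Pearson
   correlation; each immune gene set is tested on the ranked list with a
   weighted Kolmogorov–Smirnov enrichment score; the permutation p-value is
   folded into `lncres = 1 - 2p` (ES > 0) / `2p - 1` (ES < 0). Pairs with
   `lncres > 0.995` and FDR < 0.05 are significant; a lncRNA with at least
   one significant pair is called immune-related.
3. **lncRNA–pathway network** (`irlnc.network`) — the same enrichment
   machinery against a pathway collection, exported as SIF/GraphML.
4. **Subtype discovery** (`irlnc.subtype`) — consensus clustering
   (subsampled hierarchical clustering, euclidean/average linkage,
   reps=1000, pItem=0.8, pFeature=1 by default), CDF delta-area k selection,
   PCA validation, top-gene heatmap matrices.
5. **Immune profiling** (`irlnc.profile`) — GSVA-style single-sample
   pathway scores (Gaussian-kernel CDF, symmetrized-rank KS walk) and
   marker-mean cell-population scores, with exact Wilcoxon rank-sum
   between-subtype tests.

A synthetic-data generator (`irlnc.synth`) plants known immune-related
lncRNAs (latent-factor co-expression at a target correlation), DE genes and
immune subtypes, so every stage is testable without downloads. Packaged text
resources: a 17-category ImmPort-style immune gene-set GMT, GSE92681-like
(5 normal / 7 pulpitis) and GSE77459-like (6 / 6) design tables, and a
10-population marker GMT.

Two permutation nulls are available for the enrichment p-value:
`null_model: sample` (default — permutes the lncRNA across samples,
preserving mRNA co-expression, which keeps the false-discovery rate
calibrated when gene sets are themselves co-expressed) and
`null_model: gene_label` (random sets of matched size on the fixed ranked
list). Nulls are pooled across lncRNAs by default for p-value resolution
beyond `1/nperm`.

## CLI

```bash
irlnc simulate --outdir run --seed 1      # write synthetic fixtures
irlnc all --outdir run --seed 1           # run every stage in order
irlnc lncres --config my.yaml             # one stage, custom config
```

Stages: `simulate`, `de`, `lncres`, `network`, `subtype`, `profile`, `all`.
All parameters live in one YAML config (unknown keys are rejected); each
stage writes TSV/JSON artifacts plus a `manifest.json` (config hash, files
per stage) under the output directory. Defaults mirror the published
parameters: lncRES cutoff 0.995, FDR 0.05, consensus reps=1000, pItem=0.8,
pFeature=1, euclidean distance.

Example config:

```yaml
synth: {n_mrna: 2000, n_lnc: 300, n_planted_lnc: 20, rho: 0.8, seed: 7}
de: {alpha: 0.05, lfc: 1.0}
lncres: {nperm: 1000, lncres_cut: 0.995, fdr_cut: 0.05}
subtype: {k: auto, reps: 1000, p_item: 0.8}
```

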