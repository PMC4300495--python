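# modcore

Localizing disease-associated genes on a protein interaction network by
integrating four lines of evidence: the network's community structure, the
covariate-matched enrichment of curated disease gene lists, the tissue
expression pattern of the implicated module, and case/control variant
burden — all stratified by how central each gene sits in the network.

The package is aimed at systems-biology analysts who have (or can emulate)
an interactome edge list, a gene annotation table, brain-atlas-style
expression matrices, and case/control variant tables, and who want a
seeded, fully reproducible pipeline from raw inputs to an integrated
module-level report. Every input shape has a first-class synthetic
generator with planted ground truth, so the whole workflow can be
exercised — and its statistical behavior verified — without any external
data.

## The model

**Module detection.** The interactome is an undirected simple graph over
gene symbols. Communities maximize Newman–Girvan modularity

```
Q = Σ_c [ e_c/m − (d_c/2m)² ]
```

(m edges; e_c intra-module edges and d_c the degree sum of module c),
using the *first level* of the multilevel local-move heuristic: nodes move
greedily, in seeded random order, to the neighboring community with the
largest ΔQ until no single-node move helps. No coarsening pass follows, so
small dense modules are never merged into super-communities. Significance
of the observed Q comes from degree-preserving double-edge-swap rewiring
nulls, with empirical p-values always computed as (1 + b)/(1 + n).

**Matched enrichment.** Module-vs-gene-set overlaps use the upper-tail
hypergeometric test (network as universe) with Benjamini–Hochberg
correction per scan. Because curated disease lists are biased toward long,
well-studied genes, permutation tests resample from a *matched
background*: a pool of non-target genes whose CDS-length and GC-content
distributions are indistinguishable from the target's (Wilcoxon rank-sum
p > 0.05 per covariate).

**Expression dichotomy and specificity.** The module's expression matrix
(genes × tissue sections) is z-scored per gene and hierarchically
clustered on both axes (correlation distance for genes, Euclidean for
samples, average linkage, trees cut at k = 2), splitting the module into a
tissue-specific and a ubiquitous sub-component. Per-gene specificity uses
the τ index, τ = Σᵢ(1 − xᵢ/max x)/(N − 1), plus expression breadth at
pooled-quantile activity cutoffs.

**Variant burden.** Per-variant case allele counts are tested against
reference-panel frequencies with two-sided Fisher tests (BH at FDR 0.1);
panel-absent variants are scored as a rare-variant fraction with a
matched-gene permutation null; case/control cohorts are screened by
reciprocal OLS regression of allele frequencies with t-distributed
residual outlier calling; and mutated-gene fractions are profiled across
k-core strata, including a U-shape contrast statistic
S = f_top + f_bottom − 2·f_middle with a resampling null.

## Worked example

```python
from modcore import (gen_scene, louvain_partition, modularity_null_test,
                     module_set_scan, GeneSet, dichotomize)

scene = gen_scene(seed=7)              # synthetic study with planted truth
part = louvain_partition(scene.graph, seed=7)
print(f"partition: {part.n_modules} modules, Q = {part.q:.3f}")

null = modularity_null_test(scene.graph, n_random=99, seed=7)
print(f"rewiring null: max null Q = {max(null.q_null):.3f}, "
      f"empirical P = {null.p_empirical:.3g}")

disease = GeneSet("disease", frozenset(scene.disease_genes))
scan = module_set_scan(part, [disease], scene.graph.nodes())
top = min(scan, key=lambda r: r.fdr)
print(f"top module: #{top.module_id} ({top.n} genes), "
      f"overlap {top.k}/{len(disease)}, FDR = {top.fdr:.3g}")

dich = dichotomize(scene.atlas)
n1 = sum(1 for g in dich.gene_group.values() if g == 1)
print(f"expression dichotomy: {n1} tissue-specific vs "
      f"{len(dich.gene_group) - n1} ubiquitous genes")
```

prints

```
partition: 8 modules, Q = 0.745
rewiring null: max null Q = 0.249, empirical P = 0.01
top module: #5 (37 genes), overlap 30/60, FDR = 1.24e-17
expression dichotomy: 18 tissue-specific vs 19 ubiquitous genes
```

The planted disease module is recovered as the clear top hit (none of the
99 rewired networks reaches the real graph's modularity, hence the
empirical floor P = 1/100), and the module splits into its two planted
expression groups.

The same workflow is available from the shell via the `modcore` console
script (`modcore simulate`, `modularize`, `null-test`, `enrich`, `match`,
`dichotomize`, `specificity`, `de-call`, `burden`, `outliers`, `run`),
driven by a flat `key = value` config file with `[inputs]`, `[stages]` and
`[params]` sections; all randomness flows from a single `--seed`.

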