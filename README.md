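# stemtyper

A single-cell toolkit for characterizing breast-cancer cell-line
heterogeneity: adaptive per-sample quality control, difference-filtered
marker "gene vectors", cluster trees with nodal-split markers, cancer
stem cell (CSC) scoring, Markov-chain signaling-entropy stemness
scoring on protein–protein interaction (PPI) networks, receptor-status
(ER/PR/HER2) subtyping at a bimodality-derived threshold, druggable
surfaceome target prediction, and a fluorescence-image ERBB2 positivity
caller. A synthetic-data generator plants known structure for every
stage, so the whole pipeline is testable end to end without external
data.

## Who it is for

Researchers working with 10x-style scRNA-seq of cancer cell lines or
tumors who want transparent, reproducible re-implementations of the
common Seurat-era analysis conventions (LogNormalize at scale factor
10,000, VST variable genes, covariate-regressed scaling, SNN/Leiden
clustering, Wilcoxon markers) together with the less common pieces:
gene-vector derivation by the `pct.1 − pct.2` difference filter,
signaling-entropy stemness, threshold-based receptor re-subtyping, and
microfluidic image positivity calling.

## The core quantities

**Gene vectors.** For a cluster vs the rest, each gene gets a two-sided
Wilcoxon rank-sum p (Bonferroni-adjusted), the fold change
`avg_log2FC = log2((mean expm1(in)+1)/(mean expm1(out)+1))`, and the
expressing fractions `pct.1` / `pct.2`. The cluster's gene vector keeps
genes with strictly `avg_log2FC > 0.8` and `difference = pct.1 − pct.2
> 0.5` — the genes most specific to that population. The same filter is
applied at every node of the cluster tree (average-linkage dendrogram
over per-cluster centroid "average cells" in PCA space), yielding
nodal-split vectors that explain each population divergence.

**Signaling entropy rate (SR).** A cell's expression x over a PPI
network W defines a random walk `p_ij = W_ij x_j / Σ_k W_ik x_k` with
stationary distribution `π_i ∝ x_i (Wx)_i`. The entropy rate
`Σ_i π_i S_i` with `S_i = −Σ_j p_ij ln p_ij`, normalized by
`ln λ_max(W)`, gives SR ∈ [0, 1]. Diffuse, promiscuous signaling
(stem-like cells) pushes SR toward 1; expression concentrated on a few
pathways (differentiated cells) lowers it. On the complete graph with
uniform expression SR = 1 exactly; on the 4-node path it equals
`(2/3)·ln2 / ln(2cos(π/5)) ≈ 0.9603`.

**Receptor subtyping.** Per cell, a receptor (ESR1, PGR, ERBB2) is
positive when its scaled expression exceeds 0.25 (the split between the
detected-expression and overexpression modes). A cluster overexpresses
a receptor when the expressing fraction is > 0.5 and the mean exceeds
0.5; ERBB2 overexpression ⇒ HER2+, otherwise hormone-receptor
positivity ⇒ Luminal, otherwise TNBC. Mixed samples get composite
labels such as `HER2+ & TNBC`.

**Image positivity.** Cells are detected by circle-Hough on the
brightfield channel, filtered (brightness, background mask, edge band),
their disk-mean FITC brightness normalized by the cohort mean, and
classed positive/negative by an exact 1-D 2-means split (the percent
positive is reported to one decimal, e.g. 513 of 1147 → 44.7).

## Worked example

```python
from stemtyper.simulate import simulate_counts
from stemtyper.pipeline import run_pipeline, synthetic_config
from stemtyper.subtype import call_subtypes, composite_sample_label

adata, truth = simulate_counts(seed=0)          # 3 lines x 2 subclusters x 60 cells
res = run_pipeline(adata, synthetic_config(0))  # QC -> normalize -> scale -> PCA -> cluster
report = call_subtypes(res["adata"], res["labels"])
print(report[["cluster", "ERBB2_pct", "ERBB2_mean", "subtype"]].round(2))
print(composite_sample_label(report["subtype"].tolist()))
```

prints

```
kept 332 of 360 cells; mito threshold 12.7%
cluster  ERBB2_pct  ERBB2_mean subtype
      0       0.10       -0.55    TNBC
      1       0.07       -0.59 Luminal
      2       0.88        1.19   HER2+
HER2+ & Luminal & TNBC
```

The adaptive QC threshold (12.7% mitochondrial counts) is the antimode
of the bimodal percent.mito distribution and removes the planted dead
cells; the three clusters recover the three planted lines (ARI ≈ 0.99),
and each cluster's receptor call matches its planted profile: 88% of
cluster-2 cells exceed the 0.25 ERBB2 threshold with mean scaled
expression 1.19 (> 0.5 on both counts ⇒ overexpressed ⇒ HER2+).
Cluster gene vectors come out of `wilcoxon_markers` +
`filter_gene_vector`; for cluster 2 the top entries are the planted
`LINE2M*` program genes with differences of 0.6–0.7.

A command-line interface mirrors the library
(`stemtyper simulate|qc|preprocess|cluster|markers|tree|stemness|subtype|targets|image`).

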