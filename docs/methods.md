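# Methods

This note documents the models, parameter choices and numerical
decisions behind each stage of the package, what the synthetic data
does and does not emulate, and known limitations.

## Quality control

Per cell we compute `n_features` (genes with count > 0), `n_counts`
(total UMIs) and `pct_mito` (percent of counts on "MT-"-prefixed
genes, case-insensitive). Filtering keeps cells with
`n_features ≥ min`, `n_counts ≤ max`, `pct_mito ≤ max`. Defaults
(`min_features=1600`, `max_counts=65000`, mito cap 25%) sit at the
permissive ends of the per-sample ranges used for cell-line data of
this kind; a second named profile (`wu-published`: nFeature < 8,000,
nCount > 1,000, mito < 8%) matches the fixed filter used for public
tumor datasets.

**Adaptive mitochondrial cutoff.** Dying cells produce a second, high
mode in `pct_mito`. The cutoff is the antimode between the two largest
modes of a Gaussian KDE (Silverman bandwidth) evaluated on a 1,024-point
grid over [1, 30]; local maxima under 2% of the global peak are treated
as sampling artifacts, not modes. With a unimodal distribution the
cutoff falls back to the 95th percentile capped at 25%. At least 100
cells are required; below that callers must use a fixed threshold. On
samples emulating live/dead mito modes at 5%/20% the antimode lands
near 12–13%, within the 4.3–12.1% band typical of real cell-line
samples.

## Normalization, variable genes, scaling, PCA

* **Log-normalization:** `ln(1 + count·10000 / cell_total)`; sparsity
  preserved; zero-total cells are an error (filter first).
* **VST variable genes:** lowess (span 0.3) of log10(variance) vs
  log10(mean) on raw counts predicts each gene's expected sd;
  standardized values are clipped at √n_cells and genes ranked by the
  variance of the clipped z-scores; ties break by gene order. Default
  n = 2,000 (300 at synthetic scale).
* **Cell-cycle module scores:** mean(module) − mean(binned controls),
  24 expression bins, 100 controls per module gene, seeded draws. The
  S and G2M gene lists ship as editable text fixtures
  (`stemtyper/data/cell_cycle_*.txt`). Note the binned-control score of
  a planted shift is biased slightly low when module genes dominate
  their expression bin — controls are then the brightest background
  genes; tests use wide bins where this bias is negligible.
* **Scaling:** per-gene OLS residuals against centered covariates
  (pct_mito, n_counts, S score, G2M score) with intercept, z-scored and
  clipped at ±10. Covariates whose addition makes the design's
  condition number exceed 1e10 are dropped with a warning. Genes fit
  exactly by the covariates get identically-zero scaled rows rather
  than amplified rounding noise. Scaling is applied to the variable
  genes only; the receptor subtyper z-scores its genes directly from
  the normalized layer so receptors need not be variable genes.
* **PCA:** full SVD of the scaled matrix, 20 components by default;
  each component's sign is fixed so its largest-magnitude loading is
  positive, making reruns bitwise identical.

## Clustering and cluster trees

Cells are clustered on the PCA embedding: k-nearest-neighbour graph
(k = 20, Euclidean), shared-nearest-neighbour reweighting by Jaccard
overlap of neighbour sets, edges below 1/15 pruned, then Leiden
(RB-configuration modularity) at the configured resolution with a fixed
seed. Labels are ordered by decreasing cluster size.

The cluster tree agglomerates per-cluster centroids ("average cells")
in PCA space with average-linkage Euclidean clustering. PCA space was
chosen over gene space (the tree records which); both orderings agree
on the synthetic data. At each internal node, the cells of the left
branch are tested against the right branch with the Wilcoxon rank-sum
test and the result passed through the gene-vector filter; the
right-branch table is derived from the left by symmetry (two-sided p is
direction-free; fold change negated; pct columns swapped). A cluster's
cumulative gene vector concatenates its ancestral node vectors from the
root split down.

## Marker statistics

`avg_log2FC` uses base 2 with pseudocount 1 on de-logged means;
`pct.1`/`pct.2` come from the raw positivity mask, so they are
invariant to the normalization choice. Multiple testing uses Bonferroni
over the genes tested. Sorting is fully deterministic: p, then
|log2FC|, then gene symbol. p-values use the exact permutation null of
the rank-sum statistic (midranks, so ties are handled) whenever both
groups have ≤ 10 cells, and the asymptotic normal approximation with
tie correction otherwise; the exact branch is what makes small-sample
p-values reproducible against independent enumeration to 1e-10.

## Stemness scoring

**CSC sum score.** Per cluster, the sum over the 40-marker CSC vignette
of the cluster-mean normalized expression; clusters ranked descending.
Markers absent from the matrix contribute zero (with a logged count)
rather than erroring. The default vignette
(`stemtyper/data/csc_markers_40.txt`) is a curated list of published
breast CSC markers and is editable.

**Signaling entropy.** The network is restricted to its largest
connected component intersected with measured genes ("fully connected"
is read as connected, not complete; the restriction is logged). Zeros
are lifted with a pseudocount ε = max(1e-8, 0.001 × smallest positive
value), which scales with the data, so SR is exactly invariant under
uniform rescaling of the expression vector. The stationary distribution
uses the closed form π_i ∝ x_i(Wx)_i — detailed balance holds because W
is symmetric — and is verified per cell by the residual ‖πP − π‖₁
(must be < 1e-8), removing any iteration/convergence ambiguity.
Normalization divides by ln λ_max of the *weighted* adjacency
(configurable to the binarized one); networks with λ_max ≤ 1 cannot be
normalized and are an error. The batch path evaluates
`S_i = ln((Wx)_i) − [(W∘lnW)x + W(x∘ln x)]_i / (Wx)_i` with two sparse
matmuls shared across all cells and reproduces the per-cell explicit
chain to 1e-10; λ_max is computed once per batch (dense eigvalsh up to
64 nodes, Lanczos beyond). Failed cells (e.g. all-zero on the network)
are flagged, not fatal.

**Entropy–gene correlation.** Spearman rho of each gene against SR,
p from the t-approximation, Bonferroni over genes tested; genes are
classed positive/negative/null at adjusted α = 0.05, and constant genes
are flagged null. For subtype-level summaries Luminal A and B are
treated as one Luminal group.

## Receptor subtyping

The positivity threshold 0.25 is applied by default to per-gene scaled
values (z-scores of the normalized layer; the layer is recorded in the
report metadata). Overexpression requires expressing fraction > 0.5
AND mean > 0.5; plain positivity requires fraction ≥ 0.5. The
overexpression rule is a field convention; the ≥ 0.5 detection cutoff
that separates positive from negative is this package's decision, since
no standard value exists for it. Luminal A vs B are not distinguished. Cluster calls are
reported as computed; no literature override is applied even when a
line's published subtype disagrees.

## Target prediction

"Significantly expressed" is operationalized purely by expressing-
fraction floors: strictly > 0.4 for the HER2+ population, > 0.2 for the
non-HER2+ contrast, > 0.25 for generic expressed-gene selection.
Fractions are computed as integer counts divided by group size so that
boundary cases (e.g. exactly 25%) are exact. The anti-join removes
from the HER2+ set anything the contrast set expresses; ribosomal
(RPL/RPS/MRPL/MRPS) and mitochondrial (MT-) symbols are stripped; the
remainder is intersected with the surfaceome and an FDA-approved-target
catalog. Both catalogs ship as small synthetic demo TSVs
(`surfaceome_demo.tsv`, `fda_targets_demo.tsv`) with provenance
columns; real lists drop in as replacements. Response prediction flags
a cluster when the target gene clears the floor and at least half of
the pathway genes do (the ≥ 50% pathway rule is this package's
quantification); delivery and pharmacokinetics are out of scope.

## Image positivity

Detection is circle-Hough on Canny edges (σ = 2) of the normalized
brightfield, with non-maximum suppression at the minimum search radius
and an accumulator threshold expressed as a fraction of the peak.
Brightness is the disk-mean (not peak) intensity. Filters drop
detections for low brightfield brightness (the live-cell brightness
floor is a config parameter, not a fixed constant — no standard value
exists), background-mask overlap, and a configurable exclusion band
near the pen top. Normalized FITC divides by the cohort mean, so
normalized values average to exactly 1. Positivity is an exact 1-D
2-means: every split of the sorted vector is scored and the global
optimum taken, so the call is deterministic (the seed argument exists
only for API symmetry); the higher-mean class is positive. A fixed
scaled threshold of 0.5 supports conventional microscopy. Percentages
round half-up to one decimal.

## Synthetic data

The generator emulates: NB counts (mean/dispersion parameterization;
var = m + m²/θ) with log-normal library sizes (σ = 0.3); a disjoint
20-gene marker program per line at 8× and a nested 10-gene program per
subcluster at 4×; dead cells (8% by default) whose mitochondrial
fraction comes from a high mode (mean 20%, vs 5% live — bracketing the
adaptive cutoff's working range) with near-Poisson MT-gene dispersion
so the realized fraction tracks the planted one; doublets (1%) as sums
of two cells; bimodal receptor genes with per-line positive fractions
(defaults plant one HER2+, one Luminal and one TNBC line, calibrated so
positive cells clear the 0.25 scaled threshold); ribosomal decoy genes;
and five constant-mean sentinel genes (mean 10, θ = 2, exempt from
library scaling) for NB parameter-recovery checks. Background gene
means average 0.5, giving ~400 counts/cell at the 500-gene default —
deep enough that realized mitochondrial fractions resolve the two
modes.

The stemness gradient rewrites expression over a small-world
(Watts–Strogatz) network's genes as Poisson around
`budget·(s·uniform + (1−s)·concentrated)`, where the concentrated
profile puts 90% of mass on a contiguous low-branching arc of the
ring. The arc (rather than a hub neighbourhood) matters: on scale-free
graphs, concentrating expression near the hub *mimics* the
maximal-entropy walk and raises SR, inverting the intended gradient.
The images place non-overlapping disks by rejection sampling (≤ 60%
area coverage), paint dark disks on a bright brightfield and draw FITC
disk intensities from two Gaussian modes (6,000 ± 800 vs
20,000 ± 2,000 on the 16-bit scale) by true class, plus Gaussian pixel
noise.

Not emulated: ambient RNA/soup, batch effects beyond library-size
shifts, realistic transcriptome-wide gene counts, spatial structure,
and dropout beyond what NB sampling produces. Passing recovery tests
therefore shows the algorithms are correct under their stated
statistical assumptions, not that those assumptions hold in any given
real dataset.

## Problem sizes and determinism

Tests and the acceptance script run at synthetic scale: 360 cells ×
500 genes for the pipeline checks, 200 cells × 30 network genes for
stemness, 50–60 cells per image, chosen as the smallest sizes at which
the planted effects are comfortably resolvable. All randomness flows
through explicit integer seeds (numpy Generator; igraph generation
seeds Python's `random`), and a full pipeline run is bitwise
reproducible for a fixed seed.

## Known limitations

* The exact Wilcoxon branch enumerates C(n, n1) assignments and is
  only used for groups ≤ 10 per side; larger groups use the asymptotic
  approximation, as standard tools do.
* The adaptive mito cutoff assumes at most two real modes; three-mode
  mixtures will be cut at the valley between the two largest.
* The entropy scorer requires a connected effective network with
  λ_max > 1; single-edge unweighted graphs cannot be normalized.
* Cluster-level receptor calls inherit the clustering: over-merged
  clusters dilute overexpression and can flip a call to negative.
* The bundled surfaceome/FDA catalogs are synthetic demos for wiring
  and tests, not curated references.
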