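# Methods

This note documents the models and procedures implemented in `clonotrace`,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that affect results.

## Synthetic data generator

The generator (`clonotrace.simulate`) emulates a paired diagnosis/relapse
lymphoma experiment. A genome of `n_chromosomes` chromosomes with ordered,
non-overlapping gene intervals carries a clonal architecture: each subclone
inherits its parent's copy-number profile and overwrites it with private
events (integer copy numbers 0–6, never 2). Ground-truth segment tables per
subclone and expected bulk profiles per sample (proportion-weighted across
subclones, merged into constant runs) are emitted alongside the counts.

Counts follow a gamma–Poisson (negative binomial) model. For cell *i* and
gene *g*:

    count_ig ~ NB(mean = L_i * rel_g * m_ig * (c_g / 2)^alpha, size = r)

with library size `L_i` log-normal (median ≈ 5 000 UMIs, sdlog 0.35), `rel_g`
the gene's relative expression, `c_g` the copy number of the gene in the
cell's clone (2 in normal cells; homozygous deletions use the floor
`eps0 = 0.05` so c=0 remains distinguishable from c=1 without producing
all-zero genes), dosage exponent `alpha = 1` (expression proportional to
copy number; configurable to emulate dosage buffering) and shared NB size
`r = 2` (strongly overdispersed, typical of droplet scRNA-seq).

Baseline relative expressions are gamma-distributed (shape 0.4), except that
genes with marker roles are pinned to defined levels so the marker rules are
exercisable regardless of the random draw: the malignancy marker is low
outside tumor cells (0.5× the mean gene) and boosted 12-fold in malignant
cells; the two light-chain genes are solid B-lineage genes (5× mean), with
malignant cells expressing them at a 20:1 restricted:excluded ratio and
normal B-like cells expressing both; cell-type markers are moderate (2×
mean, 12× in their own type); and the S / G2M program genes are robust
proliferation markers spread over a 1–4× mean range, with set sizes (~50)
mirroring the canonical scoring lists. Cells are assigned a phase
(G1/S/G2M, defaults 70/15/15%, overridable per sample to plant a
longitudinal shift) and phase cells express their program at a 3× multiplier.
A configurable fraction of planted low-quality cells receives a 5% library
and 10× mitochondrial load.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, gene-length or GC biases, genuine transcriptional programs beyond
the marker/cycle structure, SNVs, or dosage compensation beyond the global
`alpha`. Passing tests on this generator therefore demonstrate correctness
of the inference machinery under a faithful dosage/noise model, not
robustness to every artifact of real droplet data.

## QC, normalization, clustering

Per-cell totals, detected genes and mitochondrial fraction are thresholded
per sample (defaults: ≥ 500 UMIs, ≥ 200 genes, ≤ 15% mitochondrial; these
are placeholders to be set per dataset). Cells are flagged, not removed;
after Leiden clustering of the merged data, any cluster whose flagged
fraction strictly exceeds 33% is removed wholesale, and flagged cells are
removed from surviving clusters. All-zero cells are excluded before
normalization (division by zero).

Normalization is `ln(1 + 10^4 * count / cell_total)` — a pure row operation.
Highly variable genes are ranked by a variance-stabilizing transformation: a
degree-2 polynomial fit of log10 variance on log10 mean of the raw counts
predicts each gene's sd, counts are standardized with clipping at sqrt(n),
and genes are ranked by the variance of the standardized values. The
degree-2 fit is a deliberate, deterministic stand-in for a loess smoother;
on log-log axes the count mean-variance relation is close to quadratic.

PCA keeps components individually explaining ≥ 1.5% of variance (minimum 2);
component signs are fixed so the largest-magnitude loading is positive.
Clustering uses Leiden communities (RB-configuration, seeded) on a
shared-nearest-neighbor graph: any pair of cells whose (k+1)-neighbor sets
overlap with Jaccard ≥ 1/15 is connected, with the Jaccard as edge weight —
the community-standard construction; k = 15.

## Malignant-cell identification

Calls are made per cluster (cells inherit the cluster call): the fraction of
cells with marker log-expression > 1 must reach 0.5, and the light-chain
restriction index — the absolute difference of cluster-mean log1p kappa and
lambda expression — must reach 1.0 (≈ e-fold restriction). The absolute
difference is monotone in the expression ratio, symmetric in the two chains,
and robust to zeros. The 0.5 fraction threshold operationalizes "uniformly
high" conservatively; observed marker fractions in clean malignant clusters
are ≈ 0.9.

## Copy-number inference

Genes with mean normalized expression < 0.1 over the analyzed cells are
dropped. Residuals are expression minus the per-gene reference mean
(reference = all non-malignant cells by default), clipped to ±3 to bound
outlier leverage, smoothed along genomic order with a triangular window of
101 genes (renormalized at chromosome edges, never crossing a boundary,
rows summing to exactly 1 so constant signals are conserved), and centered
by the per-cell median so the diploid baseline sits at zero.

The six-state HMM has Gaussian emissions with state means

    mu_s = kappa * ln(max(s, eps0) / 2),   s = 0..5

where `kappa = mean[e / (1 + e)]` over kept genes, `e` being the reference
mean linear expression. This calibrates for the attenuation of the log1p
transform: a gene at copy number c shows a residual of
`ln((1 + (c/2) e) / (1 + e)) ≈ (e / (1 + e)) * ln(c/2)`, not the naive
`ln(c/2)`; without the calibration, single-copy gains fall halfway between
the diploid and gain states and are systematically missed. The shared
emission sd is estimated from the reference cells' smoothed residuals,
floored at 0.05. Transitions are uniform-switch with probability 1e-6 per
alternative state (strong persistence, mirroring the sparsity of real
breakpoints); decoding is exact Viterbi in log space, vectorized across
cells, with ties broken toward state 2 and then the lower state.

**Known limitation — per-cell calls at shallow depth.** With median 5 000
UMIs and NB size 2, the per-gene log-residual noise floor is ≈ 0.8, and
smoothing produces *correlated* noise along the genome: an unlucky cell's
whole-chromosome drift can imitate a real event no matter how persistent the
transition prior. On such data a few percent of reference cell-genes are
miscalled, and per-cell event boundaries wobble. The package therefore
treats subclone-level aggregates (majority state per gene across a
subclone's cells) as the operative output — these are clean in all tested
regimes — while per-cell state matrices meet the ≥ 99% diploid-reference
bar only on deeper, less overdispersed data. Tests cover both regimes
explicitly.

Segment tables take the majority state per gene within a cell group and
merge consecutive same-state genes per chromosome into `[first gene start,
last gene end]` intervals; diploid runs are kept in the full table and
dropped from event lists.

## Subclone dynamics

Malignant cells of both timepoints are clustered jointly on smoothed
residuals (graded signal, not discrete states): PCA to 20 components, then
the same SNN-Leiden machinery (resolution 1.0) or Ward linkage cut at a
configured count. Clusters smaller than 10 cells — pruned-edge outliers —
are dissolved into the nearest large cluster by centroid distance; labels
are renumbered by decreasing size.

Resistance classification uses `r = (p_rel + eps) / (p_dg + eps)` with
`eps = 1/(2 n_dg)` (half a cell's worth — a continuity correction that
stabilizes minor clones) and threshold `theta = 0.8`: a ≤ 20% relative drop
still counts as persistent, larger drops are sensitive. Subclones with zero
diagnostic cells are relapse-specific. With multiple relapse compartments
the proportions are averaged by default; an "any compartment resistant"
rule is available.

Precursor matching computes, on a common 100 kb grid, the Jaccard index of
direction-concordant non-diploid bins (|value − 2| > 0.25) between a
diagnostic subclone profile and each relapse subclone profile; the best
match is called when the score reaches 0.5. The score is symmetric and
equals 1 exactly when the binned non-diploid patterns coincide. Fully
diploid diagnostic profiles yield an undefined score and a negative call
with a warning.

Validation against bulk retains a subclone event iff it shares at least one
base pair with a bulk segment deviating from 2 in the same direction.

## Concordance

Binning follows the stated dialect: fixed 100 kb autosomal bins, 1-based
closed coordinates (half-open internally), and the **unweighted** mean of
all distinct overlapping segments per bin; a bp-weighted mode is available
behind a flag. Uncovered bins are missing and excluded pairwise. The
diploid baseline (2) is subtracted before Spearman correlation with
average-rank ties; the result is flagged undefined for < 3 shared bins or a
constant profile. The pipeline's per-sample inferred profile is the
subclone-proportion-weighted combination of the subclones' majority-state
profiles, which cancels per-cell miscall noise in diploid regions.

## Downstream statistics

*Wilcoxon DE.* log2 fold change is the difference of group means of
log2(1 + normalized expression). Genes are tested when |l2fc| ≥ 0.25 and
detected in ≥ 10% of either group; BH correction runs over tested genes.
For small groups the two-sided p comes from exhaustive enumeration of the
rank-sum null (dynamic programming over doubled average ranks, handling
ties exactly; two-sided as twice the smaller one-sided tail, capped at 1);
larger groups use the normal approximation with tie correction. Note that
conditioning the BH family on the observed-fold-change filter inflates the
realized false-discovery proportion among tested genes — an inherent
property of filter-then-test workflows, not a miscalibration of the test.

*GSEA.* Preranked, weighted KS running sum (hit steps ∝ |score|^1, miss
steps uniform); null by gene-label permutation; p = (1 + #{|null ES| ≥
|ES|}) / (n_perm + 1); NES = ES / mean |same-sign null ES|; BH across sets;
sets below 5 genes after intersection are skipped with a note.

*Cell-cycle scoring.* Module score = mean set expression − mean expression
of bin-matched control genes (24 average-expression bins, up to 100 controls
per set gene drawn without replacement from the *non-set* genes of its bin —
excluding set genes prevents self-matching when programs share bins).
Phase: G1 if both scores ≤ 0, otherwise the larger score's phase, exact
positive ties to S with a warning. Phase shifts between timepoints are
tested per patient with Pearson's chi-square (phases absent from both
timepoints are collapsed with a warning) and BH across patients.

## Problem sizes and determinism

The standard simulated scenario used by the test suite and the acceptance
script is 22 chromosomes × 273 genes (6 006 genes) with 500 normal + 1 500
malignant cells per timepoint and three subclones at 0.90/0.09/0.01 →
0.04/0.06/0.90, all events spanning ≥ 160 genes with |copy − 2| ≥ 1; unit
tests use proportionally scaled-down genomes (with the smoothing window
scaled alongside, since a window must not span a whole chromosome). A
single seed drives genome construction, count sampling, graph clustering,
control-gene draws and permutation nulls; two runs with the same
configuration produce byte-identical output tables.

## Open design choices made here

- The expression–copy-number dosage relationship is exposed as `alpha`
  rather than fixed; the inference's emission calibration assumes the
  proportional (`alpha = 1`) regime.
- Whether subclones derive from Leiden communities or Ward trees is left to
  configuration; Leiden at resolution 1.0 is the default because CNV
  profiles form few, well-separated modes and the dense SNN graph resists
  fragmentation.
- The light-chain rule and the precursor-similarity metric are given
  explicit numeric forms (absolute log-mean difference ≥ 1; direction-
  concordant Jaccard ≥ 0.5) where qualitative descriptions are common.
- BH adjustment is not idempotent in general (re-adjusting an adjusted
  vector changes it except at fixed points such as fully collapsed ties);
  the tests assert the fixed-point and ordering properties instead.
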