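# Methods

This note documents the models and numerical choices behind `cytotype`,
what the synthetic generator does and does not emulate, and the limits of
what the test suite demonstrates.

## Intensity model and harmonization

Raw fluorescence area values are strictly positive, right-skewed and
heteroscedastic.  All analysis happens on the biexponential scale: the
forward curve is `B(y) = a·e^{b(y−w)} − c·e^{−d(y−w)} + f` with
`a, b, c, d > 0` (strictly increasing, hence invertible); data are
transformed by `y = B⁻¹(x)`.  At the default coefficients
(`a = c = 0.5`, `b = d = 1`, `f = w = 0`) the curve is exactly `sinh`, so
the transform is `asinh` — near-linear around zero, logarithmic for
bright signal.  The inverse is computed numerically so that non-default
coefficients work too: vectorized bisection bracketed by [−50, 50]
(60 halvings, bringing the bracket far below the 1e-9 tolerance) followed
by two Newton polish steps.  Monotonicity guarantees rank order within
every channel is preserved, and `transform ∘ retro` is the identity to
1e-6 relative error (both are asserted).

Batch alignment is landmark registration in transformed space.  Per
sample and channel, a Gaussian-kernel density estimate (Silverman
bandwidth, 512-point grid) is scanned for local maxima with normalized
height ≥ `density_floor` (default 0.05, below which maxima are treated as
noise); maxima closer than `merge_gap` (default 0.05) times the channel
range are merged keeping the higher.  Each surviving peak gets a
confidence score — height × |second derivative| of the density at the
maximum, min-max normalized per channel — a standard "height and
sharpness" heuristic; the expected peak count per channel (1 or 2) must
be supplied by the user, and the highest-confidence peaks become the
sample's landmarks.  The benchmark for landmark *k* is the median of
landmark *k* over samples.  Warping adds a sum of Gaussian kernels
centred on the landmarks, with σ equal to half the distance to the
nearest other landmark (a quarter of the channel range for
single-landmark channels) and kernel coefficients solved from a small
linear system so each landmark lands **exactly** on its benchmark even
when kernels overlap.  Keeping σ below half the landmark gap keeps the
warp order preserving.  Samples where no peak clears the floor are left
unshifted on that channel, with a warning.  These internals are validated
by planted batch-shift recovery (≥ 90% reduction of a +0.5 asinh-scale
offset) rather than by equivalence to any particular registration
package.

## Clustering

Markers are z-scored (constant markers dropped with a warning), reduced
by PCA (default 12 components, capped at the marker count), and a
k-nearest-neighbour graph (default k = 60, Euclidean in PC space) is
re-weighted by the Jaccard overlap of neighbour sets, pruning edges below
1/15 — the shared-nearest-neighbour convention of the major single-cell
toolkits.  Louvain modularity optimization (python-igraph
`community_multilevel`, seeded through igraph's RNG hook) with a
resolution parameter (default 0.8) produces the partition; a k-means
backend exists as a deterministic cross-check, and further backends can
be registered by name.  Intrinsic metrics are computed in PC space;
silhouette on a seeded subsample capped at 5 000 events because of its
O(n²) cost.  Stability is quantified by rerunning each resolution with
distinct seeds and scoring the adjusted Rand index against the first run;
high mean ARI with low SD of the cluster count marks a stable resolution.
The prune threshold, the silhouette cap and the seeded 2-D embedding
(UMAP when installed, first two PCs otherwise; cosmetic, never asserted
on) are this package's own documented choices.

## Reference matrix and annotation

The reference matrix holds expected relative expression per cell type and
marker in [0, 1], fused from heterogeneous sources.  Every source table
is normalized per marker — z-score across cell types, then min-max to
[0, 1]; z-scoring absorbs arbitrary source scales (a documented
invariance: multiplying a source by any positive constant leaves the
output unchanged).  Brain-RNA sources are averaged, organoid-RNA sources
are averaged, the two means are averaged and re-normalized, and the
result is combined 1:1 with the averaged normalized fluorescence table
where fluorescence rows exist; cell types without fluorescence data keep
the RNA-only profile; a final per-marker min-max restores [0, 1].  The
order (z-score then min-max) is configurable since the two phrasings
circulate interchangeably.  Antibodies whose epitopes have no coding gene
map to correlated surrogate genes (O4 → NKX6-2, SSEA-4 → its synthase
gene); the panel mapping ships as `data/marker_gene_map.csv`.  The
packaged `panel_reference()` carries the 9-type × 13-marker layout of the
neural panel but **synthetic** values regenerated deterministically from
toy sources — it is a structural fixture, not measured biology.

CAM computes, per cell, the Pearson correlation of its marker profile
against every reference row over the shared markers (≥ 3 required, < 5
warned).  Pearson invariance to positive affine transforms means raw- or
retro-scale intensities compare directly against the [0, 1] reference
without per-cell rescaling.  The critical value
`r* = t_{1−α/2,n−2}/√(t²+n−2)` gives 0.553 for 13 markers at α = 0.05.
Cells below `min_corr` stay `unassigned`; a best-vs-second gap ≤ 0.05
yields the hyphenated double label, best type first.  Negative winning
correlations (possible only under permissive thresholds such as 0.1) are
allowed and flagged `negative_r`; zero-variance cells are flagged and
unassigned.

The random-forest voice grid-searches features-per-split, tree count and
a per-tree leaf-count cap ("max nodes" is read as a maximum-leaf
constraint, the closest classifier-agnostic equivalent) with stratified
3-fold CV on an 80% training split, reporting holdout accuracy on the
remaining 20%.  Label transfer is deliberately simple: PCA fitted on the
z-scored reference, the query projected with the reference's scaling and
rotation, and an inverse-distance-weighted k-nearest-neighbour vote.  It
is not an anchor-based method and is validated only by planted-label
recovery.  Per cluster, each method's label frequencies (excluding
`unassigned` by default) give a top label; the consensus is the modal
label across methods, with alphabetical tie-breaks flagged for expert
review; the final annotation applies a user-editable cluster → label
mapping, because expert override is part of the intended workflow.

## Composition and expression statistics

Two-group composition: the statistic per cell type is the log2
fold-difference of within-group proportions, with pseudo-proportion
`0.5/N_g` substituted for empty cells (flagged).  The permutation
distribution shuffles cell-level group labels; since only per-type counts
enter the statistic, the shuffle is drawn exactly as multivariate
hypergeometric counts, and the within-group bootstrap as multinomial
counts — equivalent formulations that make thousands of simulations
cheap.  `p = (1 + #{|perm| ≥ |obs|})/(n_perm + 1)` (never below
`1/(n_perm+1)`), BH-FDR across types, percentile bootstrap CI, and a
significance call at FDR < 0.05 and |log2FD| > 0.58 (≈ 1.5-fold).
Internally groups are put in canonical order so the test is exactly
antisymmetric under swapping the caller's group order.  Multi-group
composition: one-way ANOVA F on per-sample proportions per type, with the
sample-to-group assignment permuted — samples, not cells, are the
exchangeable unit when replicate samples exist (cell-level permutation
for the multi-group design is noted as an alternative but not the
default).  Defaults: n_perm = n_boot = 1000, seeded.

Marker expression: per cell type, expression is aggregated to per-sample
means (using cells as replicates is supported but warned against — the
pseudo-replication makes everything significant), then a two-way
fixed-effects ANOVA (group × marker with interaction; statsmodels OLS,
type-II sums of squares) and Tukey HSD on group pairs within each marker
using the studentized-range distribution with the model's residual mean
square (not per-subset error estimates).

## Gate reverse-engineering

Gates are axis-aligned conjunctions of one-sided thresholds — the only
geometry transcribable into sequential rectangle gates on a sorter.  The
optimizer is a greedy forward selection re-specified from scratch:
candidate thresholds on a 100-point per-marker quantile grid, each
(marker, direction, threshold) scored by F_β (β = 1 default) of the gated
set against the target; the best refinement is added while the score
improves by more than 1e-4, then coordinate-wise re-optimization passes
re-tune each threshold until fixed point.  The selection-score trace is
kept on the result and is nondecreasing by construction.  Output steps
are ordered by addition (most informative first).  Populations with no
marker elevated above every other type lack a positive anchor threshold
and gate measurably worse — asserted comparatively on synthetic data —
which matches the practical failure mode of sorting precursor-like
populations.  Merging related populations before fitting (e.g. astrocyte
subtypes) is the caller's responsibility via relabelling.

## Synthetic data

The generator draws, per cell, a type from its sample's proportion
vector; the transformed-space intensity on marker m is
`mu0 + span·ref[type, m]` plus an optional per-sample batch offset plus
Gaussian noise (SD `noise_sd`); the raw intensity is `sinh` of that, so
the default biexponential transform inverts generation exactly (asserted
to 1e-6).  Additive Gaussian noise on the asinh scale is
multiplicative-like on the raw scale, the usual character of fluorescence
noise.  Defaults `mu0 = 1`, `span = 3` keep raw values positive for
typical draws; `noise_sd = 0.35` is a realistic stain width on the asinh
scale.  Emulated: type-specific profiles, per-sample composition with
plantable group effects, per-sample × marker batch shifts, FCS 3.1
fixture export with truth labels.  Not emulated: spectral spillover,
instrument drift within a run, doublets and debris (the pipeline consumes
pre-gated live single cells).  Passing tests therefore demonstrate
correct recovery of the assumed generative structure — they do not
certify performance on data whose noise violates these assumptions.

## Problem sizes, determinism and limitations

The test suite and acceptance script run everything at desk scale —
hundreds to ten thousand events, 2–13 markers, hundreds of permutation
replicates — sizes chosen so the planted effects are comfortably
detectable and every statistical check has known behaviour (e.g.
permutation type-I error is exact by construction, verified at 500 null
simulations within [0.03, 0.07]).  All randomness flows through explicit
seeds; the CLI fans one global seed into independent per-stage streams so
stages rerun in isolation reproduce their outputs.  Known limitations:
no spillover compensation (compensated input assumed); no FCS export of
harmonized data with original metadata; Louvain results are deterministic
per seed but not guaranteed identical across igraph versions; the
label-transfer simplification can disagree with anchor-based
implementations on hard cases; composition tests assume cells (two-group)
or samples (multi-group) are exchangeable under the null, which ignores
within-sample correlation in the two-group case.
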