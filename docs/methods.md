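# Methods

## Rank-percentile transform

Each sample is transformed independently. With 1-based average ranks over
G genes, the percentile is `(avg_rank − 1) / (G − 1)`: the top gene maps to
1, the bottom to 0, intermediate genes are uniformly spaced by rank, and
tied values share the average of their would-be ranks. An all-tied sample
maps to exactly 0.5 everywhere (the average rank is (G+1)/2), which falls
out of the formula rather than being a special case. Exact zeros in
RNA-seq tie together and share one low percentile; no other zero handling
is applied. Ranking is performed over whatever gene universe the input
matrix carries — in atlas construction that is the set of genes measurable
on every platform, restricted *before* ranking. Per-sample independence is
what makes the atlas scalable: new samples are transformed and projected
without touching the training data.

## Platform variance fraction

For each gene, a fixed-effect one-way ANOVA on platform membership. We use
population (divide-by-n) variances for both the fitted and residual parts,
so the reported fraction `σ²_p / (σ²_p + σ²_ε)` is exactly the R² of the
platform regression and is invariant to the variance convention, to adding
a constant, and to positive rescaling of a gene. It is computed in closed
form from platform group means (a single fixed effect needs no model
machinery), vectorised over genes. A constant gene has fraction 0 by the
0/0 → 0 convention. Platforms contributing a single sample trigger a
warning: their fitted mean absorbs that sample exactly and inflates the
fraction. Dataset-of-origin is deliberately *not* modelled here — residual
dataset batch is assumed to average out across the many datasets covering
each biology — but dataset identity drives the jackknife resampling.

Gene selection keeps genes with fraction strictly below the threshold
(default 0.2); boundary genes are excluded. Selection is monotone in the
threshold by construction.

## LMM diagnostic

To compare biological with technical variance per gene, percentiles are
squeezed into the open interval as `p' = (p·(G−1) + 0.5)/G` (a continuity
correction avoiding ±∞), probit-transformed, and fitted with a crossed
two-random-intercept model `y = μ + a_class + a_platform + ε`,
`a_class ~ N(0, I σ²_class)`, `a_platform ~ N(0, I σ²_Platform)`, by REML
(statsmodels MixedLM, the two factors entering as variance components of a
single all-samples group). Genes are orderable by the class/platform
variance ratio, defined as +∞ when the platform component is zero and the
class component positive. Fits that fail to converge under L-BFGS are
retried with Powell (variance components on the zero boundary commonly
trip gradient methods); genes that still fail are flagged, never silently
dropped. On data simulated from this generative model at 10 classes × 4
platforms × 5 replicates, the median estimated variance proportions are
recovered within a few percent.

## Atlas PCA

The PCA is fitted on the selected genes' percentile values, centring each
gene on its training mean and applying no variance scaling, so projection
stays a fixed linear map `coords = (p − mean) · Lᵀ`. Component signs are
fixed by flipping each loading vector so its largest-magnitude entry is
positive, making coordinates reproducible across runs and libraries. Ten
components are retained by default; the first three are the display
coordinates. A Kruskal–Wallis H statistic of each component's training
scores grouped by platform serves as a platform-dependence diagnostic
(lower is better; platforms with fewer than two samples are dropped with a
warning).

Recursive refinement re-runs everything — variance partitioning, selection,
PCA — on the sample subset. Parent and child gene lists differ because the
denominator of the variance fraction is the biology actually present: a
narrower subset re-admits genes whose platform share was diluted before
and removes others.

## Clustering and stability

K-means (10 restarts under the seed) and Ward agglomerative clustering run
on the first three components by default, the space in which the atlas is
read. Stability re-runs the *entire* pipeline per resample (jackknife:
leave one dataset out; bootstrap: samples with replacement, duplicates
collapsed to unique ids; resampling datasets instead of samples is
available via `unit="dataset"`). Each original cluster is matched to the
resample clustering by maximum Jaccard over shared samples (each cluster
independently, clusterboot-style, not an optimal assignment), and its
profile {J_b} over B resamples is summarised by the continuous H-index

    H = max { h ∈ [0,1] : #{J_b ≥ h}/B ≥ h } = max_i min(J_(i), i/B)

with J sorted descending. H = 1 iff the cluster is recovered exactly in
every resample; the definition lives in one small function so an
alternative summary can be swapped in. Resamples that lose all but one
platform, or retain fewer genes or samples than components, are skipped
and counted. The number of clusters is chosen as the k immediately before
the first decrease of the median H over an ascending k grid (default
2–10); if the median never decreases the largest k is returned with a
warning. Gene-selection stability is tracked alongside as the percentage
of the full-data gene set recovered per resample.

## Projection

New samples are rank-transformed over their full measured gene list
(`rank_over="atlas"` restricts to shared atlas genes instead), subset to
the atlas genes, and mapped through the stored means and loadings. Atlas
genes absent from the sample receive percentile 0 — the lowest rank — so
missingness biases coordinates predictably downward rather than randomly;
samples missing more than half the atlas genes trigger a distortion
warning. Single cells are not projected individually by default: dropout
makes their rank structure unlike any bulk platform. Pseudo-bulk pools
(default 9 cells, the midpoint of the 8–10 range that approximates bulk
structure in 10x data) are formed by randomly partitioning each cluster
into equal-sized pools under the seed, summing counts, and inheriting the
cluster identity; remainder cells are dropped so pools stay comparable.

The off-atlas score is the Euclidean distance from a projection to its
nearest training sample, flagged when it exceeds the 95th percentile of
the training samples' own nearest-neighbour distances (quantile
configurable). Distances are taken over **all** retained components by
default rather than the 3 display components: profiles whose cell-type
signal is orthogonal to the atlas types project near the centre of the
display space, and with many balanced cell types that central region can
sit close to a populated cluster in 3D, while over the full component
space off-atlas profiles separate cleanly from held-out profiles of
training cell types.

## Synthetic compendium

The generator emulates a curated multi-platform collection, not any
particular dataset. Per gene, baseline log2 abundance ~ N(6, 2). Each cell
type owns a disjoint block of marker genes (3% of genes per type) shifted
by +3 log2 in its samples. Half the genes are platform-affected: per
(gene, platform) they receive an additive log-shift ~ N(0, distortion 2.0)
and a mild multiplicative slope on the centred signal — gene-level
distortions that survive the per-sample rank transform, unlike a global
shift, which ranking removes. Each dataset adds a small per-gene offset
(SD 0.2, residual batch); samples add N(0, 0.5) noise. Microarray-like
platforms emit `2^log2signal` plus a gamma(2, 15) background, so
intensities are continuous and strictly positive; RNA-seq-like platforms
emit negative-binomial counts (dispersion 10) with 5% dropout, so zeros
are exact. Defaults: 2,000 genes, 10 cell types, 4 platforms (2 of each
kind), 2 datasets per platform, 5 samples per dataset per cell type —
400 samples. All draws derive from one seed.

What the generator does *not* emulate: gene-length/GC biases, unbalanced
designs (every platform sees every cell type equally — real compendia are
strongly confounded), doublets, and correlated gene modules beyond the
marker blocks. Passing recovery tests therefore demonstrates that the
pipeline removes gene-level platform distortion and preserves marker-driven
cell-type structure under balanced sampling; it does not certify behaviour
under platform–biology confounding.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at
2,000 genes × 400 samples for recovery, 600 × 128 for resampling stability
(50 bootstrap draws at the reported grid; 500 is the library default for
production use), and 50 genes × 200 samples for the LMM recovery study —
sizes at which every quantity is stable across seeds while the whole
analysis completes in seconds. The threshold-sweep diagnostic uses a
variant compendium with 8 platforms (one dataset each, distortion 1.5):
with 4 balanced platforms the platform subspace spans only 3 PCA
directions, so the median Kruskal–Wallis H over 10 components is
uninformative; 8 platforms span 7 of the 10 diagnostic components,
mirroring the platform diversity of real compendia, and the sweep averages
the median H over 4 simulation replicates because the lenient-threshold
values sit near the KW saturation ceiling where single-replicate jitter
exceeds the expected gap.

Other numerical conventions: percentile formula endpoints forced to 0 and
1; PCA via full SVD (deterministic); strict `<` at the selection threshold;
Jaccard of two empty sets defined as 0; serialisation round-trips reals at
≤ 1e-12 via `%.17g` text tables.

## Known limitations

Rank transformation discards magnitude information, so gene–gene
correlation structure is only partially preserved. The filter removes
biologically informative genes whose measurement happens to be
platform-sensitive; with few samples or few platforms the variance
fraction is noisy and selection less stable. Clustering operates in the
3D display space by default, which crowds when many cell types are
present — recursion, or clustering on more components, resolves this. The
LMM diagnostic fits one gene at a time and shares no information across
genes.
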