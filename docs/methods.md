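# Methods

## Model and assumptions

The input is a complete genes × conditions matrix **M** of log2
fold-changes, one column per condition (replicate collapsing and LFC
estimation are upstream, e.g. DESeq2 or limma). The working assumption is
the block-signal model: a biologically coherent response is a subset of
genes coordinately up- or down-regulated in a subset of conditions. Such a
block makes the genes appear as outliers on some linear combination of the
conditions, and the conditions as outliers on some linear combination of
the genes — which is exactly the structure ICA extracts, since it rotates
the whitened data to maximize the non-Gaussianity of each component.

Preprocessing standardizes each column (zero mean, unit sample sd,
n−1 denominator) and then clips entries to ±6. The clipping bound is in
post-standardization units under the default order; a `clip_first` switch
clips the raw LFCs instead, since compendium LFCs rarely exceed ±6 and
either reading of "standardize, then clip at 6" is defensible. Missing
values are a hard error: the decompositions have no mechanism for them and
silent imputation would bias every downstream statistic.

## Dual decomposition

FastICA (scikit-learn) is run on **M** (giving k *condition ICs*: signal
G, mixing A) and on **M**ᵀ (giving l *gene ICs*: signal C, mixing B), with
whitening and unit-variance components.

**Contrast function.** By default each run estimates the unmixing twice —
once with the standard logcosh contrast and once with a third-cumulant
(skewness) contrast G(u) = u³/3 — and keeps the solution with the larger
Σ(skew² + excess-kurtosis²) over its components. The reason is structural:
logcosh, exp and cube are all *even* functions, hence blind to skewness.
A one-tailed source (a set of conditions all shifted the same way — the
canonical block signal) is mainly characterized by its skew, and for such
sources an even contrast actively prefers symmetric pairwise *differences*
of two sources over the sources themselves, especially at small sample
sizes (tens of conditions). The selection score is the raw-cumulant
analogue of the D'Agostino K²; the K² Z-statistics themselves are not used
for selection because they saturate for strong deviations and can rank a
noise-amplifying direction above a clean source. With symmetric
heavy-tailed sources the logcosh solution wins the score; with one-tailed
sources the skew solution does.

**Choosing k and l.** For each candidate r in a grid (default 2, 4, …,
min(n, m, 100); one ICA run per grid point at the derived seed
`seed + r`), the per-component K² values are summed. Because ICA
*optimizes* non-Gaussianity, this sum keeps growing on pure noise —
strongly so when the sample dimension is small — so the same protocol is
also run on a matched standard-normal matrix and subtracted (parallel
analysis). The knee of the excess curve is located with the kneedle
algorithm (normalized difference curve, sensitivity 1.0; an explicit
fallback picks the point with the largest drop in incremental gain when no
knee exists, as on pure noise). When both sides are selected
automatically, the default is `tie_components=True`: k = l = the smaller
of the two knees. The block model implies a single shared signal rank, and
the transpose-side scree systematically overestimates it when conditions
are few — at inflated l the skew contrast fragments one-tailed sources
into sparser sub-indicators (which genuinely score higher on third-moment
contrasts), diluting the association coefficients downstream. Per-side
selection remains available (`tie_components=False`) and is reasonable
when the two axes are both large.

## Cluster extraction

For each IC, members are removed greedily (largest |coefficient| first,
ties broken toward the lower index; removed members join the positive or
negative set by their sign) until the D'Agostino p-value of the remainder
reaches α = 0.05, or fewer than 20 observations remain (the test is
unreliable below ~20 and undefined below 8; hitting this floor is flagged
in the extraction trace and the clusters found so far are kept). A
normal-looking component contributes no clusters; a one-tailed component
contributes one. Conditions (only) that end up in no cluster are assigned
to the component where they carry their largest absolute coefficient,
flagged as orphan-assigned; genes may remain unclustered, mirroring how
such compendia behave (a large minority of genes respond to nothing in the
panel).

## Association and significance

The outer-product statistic assoc(i,j) = GᵢᵀMCⱼ equals, up to a positive
factor, the OLS coefficient ϑᵢⱼ of the melted regression
LFC(g,c) = β₀ + Σᵢⱼ ϑᵢⱼ G[g,i]C[c,j], because ICA components are centered
and mutually uncorrelated. The regression is solved exactly through the
Kronecker structure of its normal equations (XᵀX = kron(GᵀG, CᵀC) plus the
intercept row), so the n·m-row design matrix is never materialized;
results are identical to a naive melted least-squares fit (tested) at any
compendium size.

Significance is a conjunction:

* **Wald/BH:** two-sided Wald p per coefficient from the normal reference
  (n·m observations vastly exceed k·l+1 parameters), BH-adjusted across
  the k·l family; q < 0.05.
* **Effect-size Z:** |ϑᵢⱼ| / (1.4826 · median|ϑ|) ≥ 2. The reference scale
  is deliberately robust and zero-centered: with few components a handful
  of real associations contribute a large share of a mean/sd reference and
  suppress themselves (with 3 signals among 16 coefficients the best
  achievable mean/sd z is about 2), whereas the robust scale tracks the
  typical (null) coefficient and coincides with the sd when, as in
  compendium-scale runs, real associations are sparse. It is also exactly
  invariant under IC sign flips, which the mean/sd version is not.

Each significant pair is expanded into one module per populated sign
combination of its gene and condition clusters (up to four). All
combinations are emitted rather than only mean-LFC-concordant ones — real
runs produce both up- and down-regulated gene sets against one condition
cluster — and users filter on the reported block mean. Module mean LFCs
are computed on the *original* (pre-standardization) matrix so they are in
interpretable log2 units.

### Known limitation: post-selection inference

The Wald p-values are computed as if G and C were fixed covariates, but
they are ICA components fitted to the same matrix. On pure-noise input the
components align with noise by construction and the melted regression
finds them "significant" (minimum BH q far below any threshold in every
null run); the D'Agostino extraction, applied to ICA-optimized
projections, similarly yields a few spurious tiny clusters per null run.
In simulation, about 90% of pure-noise runs emit no module at all — the
residual 10% emit a few small ones, gated by the conjunction of the Z
filter and cluster existence rather than by the nominal error rate.
Treat q-values as a ranking, not calibrated error probabilities; a sound
calibration would require data splitting or permutation nulls, which would
alter the published procedure this package implements.

## Enrichment

Gene clusters are tested against a user-supplied GMT collection with a
one-sided Fisher's exact test over a common universe (the matrix's genes),
restricted to sets with ≥ 10 members after harmonization, BH-corrected
across the full cluster × set family in one call. Reported per record:
overlap count, fold enrichment ES = (overlap/cluster)/(set/universe),
odds ratio, p, q, and overlap as a percent of the *set* size.

## Synthetic data

`synthetic.generate` produces N(0, σ²) background plus additive mean
shifts Δ on planted gene-set × condition-set blocks (overlapping blocks
add). The background is Gaussian so planted blocks are the only
non-Gaussian structure — precisely what the K² machinery is built to
detect — and the default aspect ratio (1000 genes × 60 conditions) mirrors
bacterial compendia (genes ≫ conditions). What the generator does *not*
emulate: heavy-tailed or correlated background noise, gene-gene
correlation outside modules, graded (non-uniform) effects within a block,
and batch structure. Passing recovery tests therefore demonstrates the
machinery works under the block model, not robustness to every real-data
pathology.

`recovery_scores` matches each planted module to the emitted module with
the best mean of gene- and condition-Jaccard; a planted module counts as
recovered at mean Jaccard ≥ 0.5, pair recall is the recovered fraction and
pair precision the fraction of emitted significant IC pairs that are the
best match of some recovered module.

## Problem sizes and seeds

The test suite and `scripts/acceptance.py` run the recovery study at
1000 × 60 with three disjoint 50-gene × 10-condition blocks at |Δ| = 3,
σ = 1, scree grid 2–20 step 2 (the true rank is ~4, so the demonstration
grid stops at 20), 10 seeds; the null study uses the same dimensions with
k = l = 4 fixed (the value the scree selects under the planted
conditions — on pure noise the scree has no knee by construction) over
100 seeds. Every random draw derives from one top-level seed: the
condition-side scree uses `seed + r` per grid point, the gene side an
offset stream, the parallel-analysis baseline another, so a single integer
reproduces a run bit-for-bit on the same software stack.

## Numerical choices

* Sample (n−1) standard deviation in column standardization (makes
  standardization idempotent as tested).
* FastICA tolerance 1e-4, max 500 iterations; non-convergence is recorded
  on the decomposition object, not raised.
* Rank deficiency of the regression design (condition number > 1e12)
  raises an error naming the most collinear covariate pair; distinct ICA
  components never trigger it in practice.
* Fisher p with zero overlap is exactly 1 (one-sided, P(X ≥ 0)); empty
  clusters or sets give ES 0 by convention.
* BH adjustment is the standard step-up, verified against a brute-force
  implementation to 1e-12.
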