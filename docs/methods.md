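# Methods

This note documents the models and procedures implemented in `voxgex`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic validation does and does not demonstrate.

## Scattered samples to dense maps

A donor's brain is observed at a few hundred scattered locations inside a
template-space mask. The map construction is:

1. **Border labeling.** Every mask voxel with a 6-connected neighbor
   outside the mask (or on the grid edge) is a border voxel. Each border
   voxel becomes a pseudo-point, placed at the voxel center, carrying the
   expression value of the Euclidean-nearest sample (ties go to the
   lowest sample index, for determinism). Placing pseudo-points at voxel
   centers guarantees the convex hull of the augmented set covers
   essentially the whole mask.
2. **Delaunay interpolation.** The augmented points are triangulated into
   simplices; each mask voxel center inside the hull receives the
   barycentric linear interpolant of its simplex's vertex values. This is
   exact on affine fields (verified to 1e-9 in the tests) and, being a
   convex combination of data values, can never leave the range of the
   input samples.
3. **Out-of-hull fallback.** The few voxel centers that can still fall
   outside the hull take the value of the nearest augmented point, so the
   map is defined at every mask voxel. The fallback is a declared
   convention; it affects at most a thin shell of voxels.
4. **Donor averaging.** Per-gene donor maps are averaged voxelwise.

Interpolation queries are evaluated at integer voxel coordinates (the
coordinate system is 0-based voxel indices; world space enters only
through the affine). No transformation (log, z-score) is applied before
interpolation. Coplanar point sets abort with an instruction to jitter,
rather than silently degrading to 2D.

The per-donor geometry (triangulation, barycentric weights, out-of-hull
indices) is independent of the gene, so `DonorVolumeBuilder` computes it
once and reuses it across a gene library.

## Regional enrichment

Per region, the n donor region means are tested against the brain-wide
grand mean with a two-tailed one-sample *t*-test (n − 1 df), BH-adjusted
across the tested regions; Cohen's *d* = |x̄ − μ| / s. Decisions that were
genuinely open:

- **Grand mean** = mean of region means (each region weighted equally,
  not by voxel count), computed per donor and averaged. This is exposed
  via the `reference` argument so a voxel-weighted mean can be supplied.
- The reference is treated as a **fixed constant μ**; the tested region's
  contribution to it (1/n_regions) induces a slight conservative bias,
  accepted and noted.
- Zero donor variance with a nonzero mean difference is reported as
  d = ∞, p = 0 with a `degenerate` flag rather than NaN.
- Group contrasts (e.g. one anatomical family vs another) use the Welch
  unequal-variance *t* on region-level donor-averaged means.

## Differential stability

DS of a gene = unweighted mean Spearman correlation over all unordered
donor pairs (15 for 6 donors) of the gene's spatial profile. Comparison
units are atlas region means by default (cheap, robust) with a
voxel-level mode for dense maps; both are tested. Since each donor map
rests on a limited, variable number of samples, the per-pair p-value is
computed at the **smaller** of the two donors' sample counts, using the
t-approximation for Spearman's r with n − 2 df. Decile ranks place a DS
value within a library distribution; ties take the better decile.

## Co-expression networks

- **Correlation**: Spearman per donor over that donor's samples
  (computed as Pearson on midranks, which handles constant genes
  gracefully), then a cellwise mean across donors. Spearman is used
  throughout the package for its robustness to outliers and monotone
  distortions.
- **Soft threshold**: for each candidate power β, adjacency = |r|^β with
  zero diagonal and connectivity k_i = Σ_j a_ij. The scale-free fit index
  is the R² of log10(frequency) against log10(k) over 10 log-spaced
  connectivity bins, sign-flipped when the slope is positive (a rising
  degree distribution is the opposite of scale-free). β is the smallest
  power with R² ≥ 0.8, else the argmax (flagged). The R² ≥ 0.8 rule is an
  explicit stand-in for the visual "flattening" criterion used in
  practice.
- **TOM**: TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with
  ℓ = A², unit diagonal; validated against a triple-loop oracle to 1e-12.
- **Modules**: average-linkage clustering of 1 − TOM with a **static cut**
  at `cut_height`; clusters below `min_module_size` go to background
  (module 0), survivors are relabeled by size. A static cut replaces the
  dynamic tree cut deliberately: it is deterministic and testable, and
  recovers planted modules at the package's study conditions. The default
  cut height 0.6 suits generic dissimilarities; for unsigned-|r|^6 TOMs
  of small libraries the informative merges happen high in the tree, and
  the validation uses 0.97.
- **Unsigned adjacency** is the default (|r|^β); nothing in the pipeline
  depends on the sign convention, and it is switchable by passing a
  transformed matrix.
- Agglomeration uses scipy's linkage; ties between merge candidates are
  resolved by scipy's deterministic ordering rather than an explicit
  lexicographic rule — on continuous data ties have measure zero, and
  the brute-force oracle tests agree on random matrices.
- **Hypergeometric enrichment**: one-sided P(X ≥ k); Bonferroni across
  tissue types, BH across gene-set collections, matching the two contexts
  in which such tests are conventionally reported. A utility filters a
  tissue × gene differential-expression table (adjusted p < 0.05,
  |log fold change| ≥ 0.58) into per-tissue gene sets, and another keeps
  one probe per gene by highest differential stability.

## Reverse-inference decoding

A gene map is correlated (Spearman, mask voxels) with each term's
association Z map; the top-K terms are the gene's decoded correlates.
Specificity: the gene's r for a term is ranked against every library
gene's r with that term (rank 1 = strongest; ties share the better rank).

**Social vs non-social contrast.** Each term is scored as the **median
gene expression over the term's FDR-suprathreshold voxels** (p_fdr <
0.05, pooled per term without connected-component segmentation — the
suprathreshold set is read as "the term's region"; a component mode could
be added but the pooled form is the one that yields a gene-specific
contrast). The observed statistic is a Welch *t* between social and
non-social term scores; its p-value comes from random reassignment of the
category labels to terms (term-level exchangeability), with add-one
smoothing: p = (1 + #{|t*| ≥ |t|})/(B + 1), so p is never 0 and never
below 1/(B+1). B = 5000 by default.

## Synthetic data: what it emulates, and what it does not

The generators mirror the target study's conditions: 6 donors, 363–946
samples per donor drawn uniformly without replacement over mask voxels,
54 regions, a 16³–24³ ellipsoidal mask at desk scale. Regional truth is
**region-constant**: module genes share a latent regional profile with
the latent/noise variance ratio set so the expected within-module Pearson
correlation equals `within_module_cor` exactly (background genes draw
independent profiles at matched total variance, baseline 8 arbitrary
units). Measurement noise is Gaussian (sd 0.5 by default — mid-sized
relative to the unit-scale regional variation); no noise model beyond
Gaussian is claimed. Residual misregistration is emulated as uniform
sub-voxel jitter (±0.45 voxel, strictly inside the rounding radius).
Term maps place their active set (default 8% of the mask) inside the
linked gene's top-expression regions, with Z ~ N(z_effect, 1) in active
voxels and N(0, 1) elsewhere, and BH-adjusted two-sided normal p-values
over mask voxels.

What passing on this synthetic data does **not** show: robustness to
spatial autocorrelation within regions (truth is region-constant with
i.i.d. noise; smooth within-region gradients could be added), to probe- or
batch-level artifacts, hemispheric asymmetry, or registration error
beyond sub-voxel jitter. Real-data headline numbers (specific regional
effect sizes, a particular β and R², real term ranks) depend on the real
atlases and meta-analytic libraries and are out of scope.

## Problem sizes and numerics

The validation suite and the acceptance script run at desk scale — 16³
grids (~1,500 mask voxels), 54 regions, 30-gene libraries, 6 donors ×
300–400 samples, 100–500 replicate loops, B = 199–5,000 permutations —
sizes chosen so the planted effects sit comfortably above their null
envelopes while whole-suite runs stay fast. Tolerances: interpolation
exactness 1e-9 (accumulated floating error across a barycentric solve),
oracle equivalence 1e-12, statistical recovery rates at the thresholds
stated in the tests. All RNG flows through `numpy.random.default_rng`
with explicit seeds; every stage is bit-reproducible.

## Known limitations

- The static tree cut requires a cut height appropriate to the adjacency
  scale; there is no automatic height selection.
- Region-mean DS and voxel-level DS can differ when sampling is sparse
  relative to region count; the voxel mode inherits interpolation
  smoothing.
- The scale-free criterion is a crude summary on small gene libraries
  (few connectivity bins); β selection is most meaningful at hundreds of
  genes or more.
- The enrichment t-test treats the grand mean as fixed; for very few
  regions the induced dependence is not negligible.
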