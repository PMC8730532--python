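# Methods

## Variance-component model and REML

Each quantitative trait (a voxel or a region average) is modeled as
`y = Xb + g + e` with `Var(g) = sg2 * A`, `Var(e) = se2 * I`, and `A` the
genetic relationship matrix built from sample-standardized dosages
(`A = W W' / M`). Heritability is `h2 = sg2 / (sg2 + se2)`. Allele
frequencies for standardization come from the sample itself — the default
behavior of standard GREML software — since no external reference panel is
assumed. With missing dosages, GRM entries average over the variants
observed in both samples of a pair (pairwise-complete denominators), which
avoids biasing relatedness toward zero under sparse missingness and
coincides exactly with `W W' / M` on complete data. Missing dosages are
retained through QC and mean-imputed (standardized value 0) only at
standardization time.

The restricted log-likelihood is

```
l_R(sg2, se2) = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ]
```

with `V = sg2 A + se2 I` and `P` the REML projection; the additive
constant is fixed at zero, so only likelihood differences (which are
convention-free) matter. Optimization is average-information REML:
3 EM warm-up iterations, then AI updates with step-halving whenever a
proposed step lowers the restricted likelihood, convergence at
`|delta l_R| < 1e-8`, at most 100 iterations. Both components are
constrained to at least `1e-6 * Var(y)`, matching the convention of
widely used GREML tools; a fit is flagged `constrained` when a component
ends on that floor. Every fit runs in the eigenbasis of `A`, where `V` is
diagonal, so a phenotype matrix (thousands of voxels) reuses a single
eigendecomposition; a dense-algebra evaluation of the same likelihood is
kept as an independent cross-check path and the two agree to 1e-8 in the
tests.

The null model fixes `sg2 = 0`, where the residual variance has the
closed form `y'My/(N - C)`. The LRT p-value uses the boundary mixture
`0.5*chi2(0) + 0.5*chi2(1)`, i.e. `p = 0.5 * Pr(chi2_1 >= LRT)`, clamped
to (0, 1]; a fit on the floor with no likelihood gain reports exactly
p = 0.5. The standard error of `h2` comes from the delta method applied to
the inverse AI matrix at the optimum; when a component is constrained the
SE is still reported but is not trustworthy (the sampling distribution is
a boundary mixture).

A consequence worth stating explicitly: for a truly non-heritable trait
the REML estimate of `sg2` lands on the floor with probability about 1/2,
not 1 — the classic boundary result for variance components. Our 50-replicate
measurement at N = 400 gives 44–60% of null fits constrained depending on
seed. Selected *regions* of insignificant voxels, by contrast, are at the
floor almost always, because the selection itself conditions on weak
genetic signal.

## Quality control

Variant filters, applied jointly on the input matrix and attributed in the
report to the first failing filter in order: folded MAF > 0.001; missing
fraction <= 0.02; exact Hardy-Weinberg test p >= 1e-6. The HWE test is the
exact conditional test on the heterozygote count (chi-square is offered as
an option but the 1e-6 threshold lives in the tail where the chi-square
approximation is poor). Samples with >= 5% missingness over the retained
variants are then removed; variant-then-sample order is a fixed convention.
Two optional, default-off simplifications replace pedigree-based pruning:
a greedy GRM-based relatedness prune (drop one member of each pair with
relatedness > 0.25) and a heterozygosity outlier rule (> 3 SD from the
mean rate).

## Maps, smoothing, and region extraction

Background voxels — exactly zero in every subject — are excluded at
vectorization; remaining voxels are kept in lexicographic coordinate
order. When painting per-voxel statistics back into volumes, p-value maps
fill the background with 1 (never significant) so that smoothing near mask
edges dilutes toward insignificance instead of manufacturing significant
borders; heritability and label maps fill with 0.

The p-value volume is smoothed with a separable Gaussian (default sigma
0.5 voxels, truncation 4 sigma, reflect boundary) over the full array,
background included. Selection then marks in-mask voxels: significant arm,
smoothed p < alpha (default 0.05) ranked ascending; insignificant arm,
smoothed p >= alpha ranked descending. The top `ceil(fraction * n)` are
kept, ties at the cut broken lexicographically. Connected components use a
26-neighborhood by default (6/18 configurable), labeled in first-encounter
scan order. Fixed order of operations: smooth, then select, then label.
Region traits are unweighted means of member-voxel traits per subject;
atlas regions are nonzero atlas labels intersected with the phenotype mask
(labels entirely outside the mask are dropped with a warning). No minimum
region size is imposed by default (`min_region_voxels` exists for
practical use). Note that sigma = 0.5 is below the lattice-sampling limit
for kernel composition — two such smooths do not equal one sqrt(2)-scaled
smooth to better than ~0.06 — which is why the semigroup check in the test
suite runs at sigma = 1; the sigma = 0.5 smoothing itself is verified
exactly against direct dense convolution.

## Synthetic study design

The generator exists so every stage is testable at desk scale without
controlled-access genotype or imaging data. Defaults:

- **Genotypes**: N = 400 subjects, M = 2000 biallelic variants, per-variant
  MAF uniform on (0.05, 0.5). Subjects come in 50 family blocks of 8 full
  siblings (two simulated parental haplotype pairs per block, inheritance
  independent across variants), unrelated across blocks. The blocks widen
  the GRM eigenvalue spectrum, which sharpens small-N heritability
  estimation; this is a test-design choice, not a cohort claim. Sibling
  pairs realize relatedness 0.5 as a population-genetics identity, checked
  empirically. Family structure also mildly inflates the HWE statistic, so
  QC may drop a handful of simulated variants; that is realistic and
  harmless.
- **Volumes**: 16^3 grid; an inscribed ellipsoidal "brain" mask (outside
  voxels exactly 0, exercising background filtering). Two spherical blobs
  (radius 2.5, centers (5.5,5.5,6.5) and (10.5,10.5,9.5)) carry true
  heritability 0.8 and 0.6; background voxels are non-heritable.
- **Soft blob edges**: true heritability falls linearly from the core
  value to 0 over a 1-voxel shell. Registered, upstream-smoothed tracer
  images do not have voxel-sharp effect boundaries, and the edge profile
  matters here: the pipeline smooths the p-value map before thresholding,
  which erodes roughly one voxel layer from any significance boundary
  (in-mask null p-values average ~0.37 under the mixture construction, so
  a surface voxel with two or more exposed faces is pushed above alpha).
  For a hard-edged sphere small enough to fit a 16^3 volume, that erosion
  alone caps the achievable overlap with the true blob at Dice ~0.5-0.7;
  with the soft edge the shell absorbs the erosion and the full-signal
  core is recovered (Dice ~0.8 across seeds). The ground-truth mask of a
  blob is its full-signal core.
- **Phenotypes**: per voxel, `y = offset + b_age*(age - mean) + b_sex*sex
  + sqrt(h2)*g + sqrt(1-h2)*e`, with `g = L z` (L a PSD square root of
  the GRM; negative eigenvalues from floating-point are clipped at zero)
  and `z` shared by all voxels of a blob, so blob-average traits are at
  least as heritable as member voxels — mirroring the empirical finding
  that aggregating significant voxels yields very high region-level
  estimates. Noise is independent per voxel. Total variance is 1 in
  expectation (the GRM diagonal averages ~1). Age is N(76.9, 7.5^2) and
  sex Bernoulli(0.54), typical of an elderly imaging cohort; covariate
  effects default to b_age = 0.01 per year and b_sex = 0.1.
- **Toy atlas**: multi-source BFS growth from random in-mask seeds, giving
  contiguous labels that exactly partition the mask.

What the generator does *not* emulate: linkage disequilibrium, genotyping
error, population stratification beyond family blocks, PET noise physics,
spatial autocorrelation of the noise, registration artifacts. Passing
tests therefore demonstrate correctness of the estimator and the
extraction logic under the stated model, not robustness to those
real-data complications.

## Problem sizes and numerical choices

The default study (1472 in-mask voxels, N = 400, C = 13 covariates) runs
the full pipeline in a few seconds on one core because all per-voxel fits
share one GRM eigendecomposition; the recovery experiment uses 50
replicates per truth value. Degenerate phenotype columns (constant or
non-finite) are recorded with an explicit failure status and skipped, and
failed voxels enter the maps as h2 = 0 / p = 1. Eigenvector signs are
fixed (largest-magnitude element positive) and eigenvalue ties break by
index so outputs are bit-reproducible; the pipeline is deterministic given
the design seed, which is the only source of randomness.

## Known limitations

- Single GRM only: no partitioned heritability, bivariate models, or
  gene-environment components.
- Mean imputation of missing dosages only; no phasing or imputation.
- The AI matrix can be near-singular when a component sits on the floor;
  the fit falls back to EM-style steps and flags the result.
- Atlas averages exclude background voxels inside atlas labels; with
  severely misaligned atlases this silently shrinks regions (a warning
  counts dropped voxels).
- Region counts on synthetic data depend on the blob design and are not
  comparable to counts from real high-resolution data.
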