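# Methods

`facemod` implements a modular, multivariate association analysis between
candidate SNPs and 3D facial shape, exercised end-to-end on synthetic cohorts
because the cohorts this style of analysis was designed for (dense facial
surface scans with genotypes) are access-controlled. This note records the
model, the estimators, the numerical choices, and what the synthetic data do
and do not establish.

## Shape model and preprocessing

A face is a configuration of L homologous quasi-landmarks in mm,
`X ∈ R^{L×3}`. Preprocessing follows standard geometric morphometrics:

1. **Symmetrization.** Each configuration is averaged with its reflected,
   relabeled mirror image: `X_sym = ½(X + P·reflect_x(X))`, with `P` the
   involution pairing bilateral landmarks. The output is exactly invariant
   under reflect-and-relabel and midline landmarks land exactly on the
   midsagittal plane (the averaging is bitwise symmetric). Only the
   mirror-symmetric component of any shape effect survives this step — a
   fact the synthetic generator must respect (below).
2. **Generalized Procrustes superimposition (GPA).** Configurations are
   centered, scaled to unit centroid size, and iteratively rotated to the
   evolving consensus (SVD orthogonal Procrustes with determinant correction,
   so reflections are excluded) until the consensus moves less than `tol`
   (default 1e-10 RMS). GPA is only defined up to a global rotation, so the
   converged consensus is rotated onto its principal axes with a fixed sign
   convention; alignment is then invariant to the input orientation and to
   subject order. *Facial size* is the pre-scaling centroid size — the
   standard size measure — and feeds the covariate block.
3. **QC.** Outlier faces are flagged by the Mahalanobis distance between each
   subject and the mean face, computed in the PCA subspace holding 98% of the
   variance (the full-space covariance is singular when 3L > n), standardized
   across subjects, flag at z > 2. Flagged subjects are reported, not
   deleted; a strict mode drops them.
4. **Covariate adjustment.** Shape (flattened aligned coordinates) and each
   SNP dosage are residualized per cohort on age, age², sex, weight, height,
   facial size and four ancestry axes via partial least squares, with the
   component count defaulting to the covariate rank — at that setting PLS
   spans the covariate column space and the residuals equal OLS residuals,
   which is the most reproducible choice; smaller counts are available for
   under-determined designs. Adjusted *configurations* are rebuilt as
   consensus + residual so later per-module Procrustes fits operate on valid
   shapes. Adjustment is cohort-local throughout.

## Segmentation

Landmark co-variation is measured with Escoufier's RV coefficient between the
two n×3 coordinate blocks, giving an L×L structural similarity matrix
(computed in one pass from the 3L×3L cross-product matrix). The matrix is cut
by recursive spectral bisection: the sign of the Fiedler vector of the
symmetric normalized Laplacian, with the eigenvector sign fixed by the first
index, zeros assigned to the smaller side, and a fallback to connected
components for disconnected graphs. Depth 5 yields the strictly bifurcating
63-module hierarchy (1, 2, 4, 8, 16, 32 modules per level).

Two additions matter in practice:

- **Perfectly covarying groups are never split.** After symmetrization,
  mirror-paired landmarks carry identical information (RV exactly 1), and
  eigen-solver tie-breaking would otherwise scatter them. Indices with
  similarity ≥ 1−1e-9 are contracted into groups, the quotient graph is
  bisected, and groups move whole; a plain bisection is the last resort when
  indivisible groups cannot satisfy the size floor.
- **Minimum module size.** A module needs ≥ 3 landmarks to support its own
  Procrustes fit. With L ≥ 3·2^depth the bisection enforces the floor
  (weakest-loading indices move across); with fewer landmarks the pipeline
  instead skips undersized modules and records them.

An optional k-nearest-neighbour adjacency mask on the template enforces
spatial contiguity of modules; it is off by default and both modes are
tested. Segmentation always pools the adjusted shapes of all cohorts.

## Module phenotypes

Each module is re-superimposed with its own GPA (not sliced from the
full-face alignment), flattened, centered and decomposed by PCA
(eigendecomposition of the covariance; PC signs fixed by the
largest-magnitude loading). The retained dimension k comes from Horn-style
parallel analysis: observed eigenvalues are compared rank by rank against the
95th percentile of eigenvalues of column-permuted copies of the data, and k
is the leading run of exceedances (forced ≥ 1). Defaults are 200
permutations on the full data. The simulation studies use a documented
economy setting — 50 permutations, spectra from a 500-subject row subsample
(the same subsample feeds observed and null spectra, keeping the comparison
matched), truncated at rank 30 via a two-pass randomized eigensolver — chosen
so the full 63-module sweep stays interactive; selection differs from the
full setting by at most ±1 component in testing.

## Association testing and meta-analysis

For one SNP and one module, the test is a canonical correlation between the
dosage (a single variable) and the module's k PC scores: CC is the multiple
correlation of dosage on scores, and Rao's F approximation to Wilks'
Λ = 1 − CC² reduces, for a single-variable block, to the exact
overall-regression F. Because both sides were residualized on c = 10
covariates, the pipeline uses (k, n − k − 1 − c) degrees of freedom; with the
naive n − k − 1 denominator the test is measurably anti-conservative
(≈ 0.058 at nominal 0.05 for n = 400, k = 10). The canonical direction is
the normalized regression direction, oriented so the canonical variate
correlates positively with dosage.

Replication is projection-based: a replication cohort's aligned module shapes
are rotated onto the discovery module consensus, centered with the discovery
mean, and projected onto the discovery PC basis and canonical loadings,
yielding a genetic effect score per replication subject. The score is
regressed on the replication dosage and tested one-sided (upper tail, n−2−c
dof) in the orientation fixed by discovery. Three rotations are run
round-robin, each cohort once the discovery set; the three p-values per
rotation (one discovery, two replication) combine by Stouffer's method,
unweighted by default (√n weights optional).

Two numerical points. First, planted effects can drive p-values below the
smallest positive double; all tails are therefore computed in log space
(incomplete-beta log-tails with leading-order asymptotic fallbacks), z-scores
obtained via `ndtri_exp`, and the Stouffer Z carried alongside the reported
p (floored at 1e-300) so module rankings never tie at p = 0. Second, the
module sweep is vectorized over SNPs; the per-SNP entry point is a thin
wrapper over the same code path, asserted equal in tests.

Multiple testing follows the effective-number-of-tests route: Li–Ji Meff from
the eigenvalues of a correlation matrix — between-module correlations of
first-PC scores (averaged over cohorts) and between-SNP dosage correlations —
and the study-wide cutoff is α / (Meff_modules × Meff_SNPs × 3 rotations).
With the literature's 37 modules, 30 SNPs and 3 rotations at α = 0.05 this
reproduces the printed 1.50e-05 cutoff; the ratio arm's 42-SNP cutoff is
0.00119. Li–Ji is reported both raw and rounded to an integer.

SNPs with minor-allele frequency below 5% in *any* cohort are excluded before
testing (folded dosage-mean MAF per cohort), with an exclusion report naming
the offending cohort.

## Facial ratios

Five width-to-height-style ratios are quotients of inter-landmark distances
on the raw (mm) configurations — total and upper facial width-to-height,
lower-face-to-face-height, width-to-lower-height, and bizygomatic/bigonial
prominence. The exact endpoint set is configuration, not constants: the
definitions are literature-standard stand-ins. Each ratio is residualized on
sex, age and body size (height), then regressed on dosage plus four ancestry
axes; the additive slope is tested two-sided against α/n_SNPs. Subgroup
reruns (male, female, post-pubertal: age > 14 for the ratio arm, > 15 for the
module arm) filter rows before adjustment; constant covariate columns (sex in
single-sex subsets) are dropped from the stage-1 design.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
facial images. A deterministic, bilaterally symmetric template (9 named
anatomical landmarks — bizygomatic width 130 mm, nasion–gnathion 110 mm — on
an ellipsoidal layout) anchors everything. Per cohort: ages uniform on
cohort-specific ranges (3–40, 18–83, 14–17 years, mirroring the three-cohort
design), sex Bernoulli(½), sex-shifted normal height/weight, standard-normal
ancestry axes; genotypes Hardy–Weinberg at stated MAFs (hard calls, or
noisy dosages in [0,2]); shape = template + covariate displacement fields
(radial growth for age/age², a lower-face dimorphism field for sex, smooth
random fields for height/weight/ancestry) + SNP effects + spatially
correlated residual (distance-decaying Gaussian kernel, scale 25 mm, SD 2 mm
per coordinate) — then allometric scaling and random rigid nuisance
transforms so superimposition has real work to do. Everything derives from
one seed.

**Planted SNP effects** are the delicate part, and their geometry was driven
by the generator's own contract (the effect must be *localized to the target
module* and must survive the pipeline as a *shape* effect):

- The target module comes from a reference tree built on the *symmetrized*
  residual kernel — after symmetrization mirror pairs covary perfectly, so
  data-driven modules are bilateral; a lateralized plant would leak half its
  energy to mirror partners.
- For a module with two sub-modules the field is a *relative pose contrast*:
  one child translates along the module's mean outward normal, the other
  counter-translates so the module's net translation vanishes — anatomically,
  a relative protrusion of one sub-region against the other (in the mandible,
  chin against jaw body). This is the displacement geometry that genuinely
  belongs to the module: restricted to either child it is a pure translation,
  absorbed completely by the child's own Procrustes fit, so no descendant can
  detect it. Amplitude-bump fields fail this property — under spatially
  smooth residual correlation the module's core child becomes the *best*
  detector of a Gaussian bump and wins the evidence race against the module
  itself. A wide Gaussian bump along outward normals remains the fallback for
  leaf modules without children.
- The field is symmetrized, orthogonalized against the module's
  similarity-transform tangent space (translations, rotations, scaling —
  otherwise per-module GPA absorbs it), and normalized to unit Frobenius
  norm: β is the total module displacement in mm per alternate allele. At
  the recovery study's β = 0.5 residual-SD this is a moderate effect (best
  meta p ≈ 1e-25..1e-45 at n ≈ 3000); much stronger normalizations saturate
  the tests, and in that regime ancestor modules — which lose less of the
  signal to their own Procrustes fit while the dimension penalty becomes
  negligible — systematically edge out the planted module.

What passing tests show, and do not show: the pipeline is calibrated and
localizes module-supported additive effects under Gaussian, spatially
correlated residuals with complete data. Real facial surfaces bring
registration error, missing data, non-Gaussian variation, relatedness and LD
between candidate SNPs, none of which the generator emulates.

## Validation studies

- **Null calibration.** Four independent three-cohort studies (500/400/600
  subjects, 96 landmarks, 100 effect-free SNPs each) are pushed through the
  complete pipeline and the 75,600 meta p-values pooled; rejection at
  α = 0.05 stays within 0.05 ± 0.01. Pooling across studies matters: within
  one study all SNPs share the same shape data, so the rate's Monte-Carlo
  variance is dominated by the study draw.
- **Recovery.** Fifty replicates with one planted mandibular SNP
  (β = 0.5 residual-SD per allele, MAF 0.2, cohorts 1000/700/1300,
  128 landmarks). The association sweep runs over the generator's 63-module
  tree (the planted module is by definition one of its modules); the planted
  module must attain the best meta evidence (maximal Stouffer Z) in ≥ 80% of
  replicates. The data-driven segmentation is re-estimated per replicate and
  summarized separately by Jaccard overlap. The SNP's displacement field
  (pooled regression of adjusted coordinates on residualized dosage) must
  concentrate > 80% of its energy on the planted landmarks; energies are
  debiased at the aggregate level (Σ b² − Σ SE², floored at zero) because raw
  squared slopes carry a sampling-variance floor on all 3L coordinates that
  caps the raw fraction near 0.75 at these sample sizes regardless of
  localization quality.

Problem sizes throughout (cohort sizes, landmark counts, permutation and
replicate numbers) are the package's own choices, set so each study carries
the Monte-Carlo precision its assertion needs.

## Known limitations

- The cross-cohort projection assumes replication faces can be mapped into
  the discovery module frame by a rigid rotation of their own GPA output;
  with grossly different cohort mean shapes a fuller re-alignment would be
  needed.
- Li–Ji inputs (first-PC correlations between modules; dosage correlations
  between SNPs) are one defensible choice among several; both matrices are
  exposed.
- Parallel analysis on a row subsample with truncated randomized spectra is
  an approximation, validated here only to ±1 retained component against the
  full computation.
- Missing dosages and missing landmarks are rejected, not imputed.
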