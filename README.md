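# facemod

Candidate-SNP association analysis for modular 3D facial shape.

Human faces vary in coordinated regional patterns, and individual common
variants shift those patterns by fractions of a millimetre. Detecting such
effects requires treating facial shape as a *multivariate* phenotype at many
spatial scales rather than as a handful of univariate measurements. This
package implements that analysis end to end for geneticists and
morphometricians: dense-landmark preprocessing, data-driven hierarchical
segmentation of the face into 63 modules, per-module multivariate phenotypes,
a projection-based round-robin meta-analysis across three cohorts, and a
classical facial-ratio association arm. Because the cohorts this design
targets are access-controlled, the package ships a first-class synthetic-data
generator that reproduces the statistical structure the analysis assumes —
every stage is testable, calibrated and power-checked without any download.

## The analysis

Given cohorts of landmark configurations `X_i ∈ R^{L×3}` (mm), dosage
genotypes `g ∈ [0,2]` and covariates:

1. **Symmetrize** each face with its reflected, relabeled mirror image, then
   remove position, orientation and scale by **generalized Procrustes
   analysis**; flag outliers by Mahalanobis distance to the mean face
   (z > 2, in the 98%-variance PC subspace). Centroid size is kept as the
   facial-size covariate.
2. **Adjust** shape and dosage per cohort for age, age², sex, weight, height,
   facial size and four ancestry axes by partial least squares (full
   component count ⇒ OLS-equivalent residuals).
3. **Segment**: Escoufier's RV coefficient between every pair of landmarks'
   (n×3) blocks gives a structural similarity matrix; recursive spectral
   bisection (Fiedler vector of the normalized Laplacian) on the pooled
   adjusted shapes yields a strictly bifurcating hierarchy — 63 modules at
   depth 5 (1, 2, 4, 8, 16, 32 per level).
4. **Phenotype** each module: its own Procrustes fit, PCA, and Horn parallel
   analysis to retain k components.
5. **Associate**: for each SNP and module, canonical correlation between
   dosage and the k PC scores, tested by Rao's F on Wilks' Λ = 1 − CC²
   (exact overall-regression F for a single genetic variable, with degrees of
   freedom reduced by the 10 residualized covariates). Replication cohorts
   are projected onto the discovery canonical direction — a *genetic effect
   score* — and tested one-sided by the regression-slope t. Each of the three
   round-robin rotations combines its discovery and two replication p-values
   with **Stouffer's method**.
6. **Correct**: Li–Ji effective numbers of modules and SNPs set the
   Bonferroni cutoff α / (Meff_modules × Meff_SNPs × 3). With the
   literature's 37 modules, 30 SNPs and 3 rotations this is 1.50e-05; the
   42-SNP ratio arm uses 0.05/42 ≈ 1.19e-03.
7. **Ratios**: five width-to-height-style ratios from named landmarks,
   adjusted for sex, age and body size, tested per SNP with ancestry
   covariates, two-sided, in the full sample and male / female /
   post-pubertal subgroups.

SNPs with MAF < 5% in any cohort are excluded up front. See
`docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

The numbered scripts under `analysis/` tell the story on a demo study —
three cohorts (300/200/400 subjects, 96 landmarks), ten SNPs of which two are
rare and one carries a planted mandibular effect of 1.5 mm total displacement
per allele:

```bash
python analysis/01_simulate_cohorts.py   # simulate + write cohorts
python analysis/02_segment_face.py       # 63-module hierarchy
python analysis/03_module_associations.py
python analysis/04_facial_ratios.py
python analysis/05_calibration_and_recovery.py
```

`03_module_associations.py` prints, among other things:

```
Round-robin CCA meta-analysis
  effective modules (Li-Ji): 37 (raw 36.905)
  effective SNPs   (Li-Ji): 8 (raw 8.000)
  rotations: 3   alpha: 0.05
  study-wide threshold: 5.631e-05

snp            module    rotation      CC     p_disc     p_meta  sig
rs_planted         52     cohortC   0.548   1.12e-30   6.53e-63  *
rs_planted         52     cohortA   0.605   4.47e-29   9.37e-63  *
...
planted SNP best hit: module 52 (cohortC discovery), CC = 0.548, meta p = 6.53e-63
best meta p among effect-free SNPs: 5.32e-04
```

Reading: the MAF filter removed the two rare SNPs; the Li–Ji correction on
this study's own data leaves 37 effective modules and 8 effective SNPs, so
study-wide significance requires p < 5.6e-05. The planted SNP's strongest
signals sit in mandibular modules in all three rotations (CC ≈ 0.4–0.6 is the
canonical correlation between dosage and the module's PC scores), far beyond
the threshold, while the best effect-free SNP stays above it. The ratio arm
(`04`) shows the same SNP nudging lower-face ratios without reaching its
Bonferroni cutoff — ratios compress shape to scalars and pay for it in power.

A single-command variant of the same pipeline, driven by a YAML config:

```bash
facemod all --config config.yaml --seed 7 --out results/run
facemod report --out results/run
```

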