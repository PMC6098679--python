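# Methods

This note documents the models implemented in berrymorph, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions that matter for reproducibility.

## Fruit silhouette model

Fruit are modelled as a two-parameter silhouette family that spans the
three shape classes seen in cranberry — round, elongated, bell-shaped —
with the smallest parameterization that makes bell and elongated
distinguishable topologically but not by LW ratio alone:

* **round / elongated**: superellipse |x/a|ⁿ + |y/b|ⁿ ≤ 1 with semi-axes
  a ≥ b (mm) and exponent n ≥ 1 (n = 2 is an ellipse);
* **bell**: half-width profile w(t) = b·(1 − k·t)·(1 − t²)^(1/n) at axial
  coordinate t ∈ [−1, 1], with asymmetry k ∈ (0, 1) producing one blunt
  and one tapered end.

Masks are rasterized by classifying pixel centres; objects below 25 px
are rejected as degenerate. Scenes follow the acquisition protocol
emulated throughout: 25 fruit per genotype, six reference circles of
known diameter (default 25.4 mm) along each of the top and bottom edges,
dark objects on a light background, no touching objects (rejection
sampling on padded bounding boxes; an infeasible layout raises a packing
error rather than overlapping).

Fruit-to-fruit variability enters through the shape parameters (a, b, k),
not through pixel noise, so segmentation stays trivial and tests isolate
descriptor behaviour; optional Gaussian pixel noise is available behind
`SceneSpec.pixel_noise_sd`.

## Basic descriptors

Length and width are the longest and shortest chords through the object
centroid, sampled at 360 angles over [0, π) with 0.5 px steps; if the
centroid falls outside the foreground (strongly non-convex masks) the
longest intersection run of the line is used instead. This is a literal
"determined by the centroid" convention; Feret diameters would differ for
bell shapes. Area is the foreground pixel count times mm²/px².
Eccentricity is that of the second-central-moment ellipse, clipped to
[0, 1] — the 0-circle-to-1-segment convention. Rotation invariance holds
to ~1% (length/width/area) and 0.02 (eccentricity) under rasterization.

Scale calibration divides the known reference diameter by the mean
equivalent-area-circle diameter of the segmented reference circles;
references with a coefficient of variation above 5% (default) indicate a
segmentation problem and raise an error. Reference circles are recognized
by area (within 25% of the expected circle area for the configured
expected diameter) and eccentricity ≤ 0.3.

## Topological signature

Each mask yields a 120-value signature: 4 annuli × 30-point Euler
characteristic curves (ECCs), innermost annulus first.

* **Density.** Gaussian kernel sum with σ = 0.2·r_max (r_max = centroid
  to farthest foreground pixel), computed by Gaussian filtering of the
  source indicator and min–max normalized to [0, 1] on the foreground.
  The kernel source defaults to **all foreground pixels**; a contour-only
  mode is available (`density_source="contour"`). The foreground source
  was chosen as default because the contour indicator of a rasterized
  shape is angularly anisotropic (staircase effect), which measurably
  degrades the PC1–elongation correlation on a round-to-elongated panel
  (~0.75 vs ~0.84), while both modes separate bell from elongated
  equally well.
* **Annuli.** Four concentric bins of equal radial width in normalized
  centroid distance; the last bin is closed so the farthest pixel belongs
  to annulus 4. Equal width (not equal area) keeps the bins concentric
  rings of equal radial step.
* **ECC.** χ of the superlevel set {density ≥ t} within each annulus at
  30 thresholds evenly spaced on [0, 1]. Superlevel vs sublevel is
  config-exposed (`direction`); the global [0, 1] threshold grid makes
  curves comparable across fruit without any dataset-level pass.
* **χ itself** is computed by bit-quad counting under the (8, 4)
  convention — 8-connected foreground components minus 4-connected
  enclosed holes — and is verified exactly against an independent
  flood-fill implementation.

PCA of the signature matrix is column-centred SVD; component signs follow
a fixed rule (largest-|loading| entry positive) because the second
component of shape panels is otherwise sign-unstable between panels. In
the pipeline, PCA is fitted per year (a pooled mode is a one-line change
in the orchestrator); scores from different years are therefore not on a
common scale, which matches the per-year analyses downstream.

## Synthetic cross and phenotypes

The four-way cross (offspring classes ac, ad, bc, bd) is simulated per
linkage group by drawing each parental gamete as a two-state Markov chain
along the map with Haldane (no-interference) switch probabilities
r = (1 − e^(−2d/100))/2; maternal and paternal meioses are independent.
Default map: 976 markers evenly spaced over 12 groups of 100 cM; default
family size 351. Planted QTL are simulated as extra hidden loci so their
true genotype classes are known exactly.

Phenotypes are built on the genotype-mean scale with total variance 1:
planted QTL effects (a class-effect pattern rescaled to its target
variance fraction), a polygenic term (random effects summed over all
marker indicators, orthogonalized against the planted QTL classes so the
fractions compose additively, then rescaled), an additive year shift
(SD 0.25 by default), and per-fruit noise whose SD is chosen so the
25-fruit mean has residual variance 1 − h²_total. The within-genotype
fruit-to-fruit variance is an assumption of this generator, not an
estimate from data. Gene-by-environment interaction is not modelled
beyond independent residual draws. For image simulations, two (optionally
three) latent genetic traits drive geometry: size (log mean radius,
scale 0.10 per latent SD around 8 mm), elongation (log a/b, scale 0.20
around a baseline of 0.25), and bell asymmetry; size and shape are
genetically independent by default.

## Kinship, REML, heritability

Each marker is split into two biallelic indicators (maternal allele = a;
paternal allele = c), centred by observed frequency, with missing values
mean-imputed and monomorphic columns dropped;
**A** = WW′ / Σₖ pₖ(1 − pₖ) over all indicator columns. Inside a single
full-sib family every offspring draws its alleles independently, so this
is a *Mendelian-sampling* relationship matrix: diagonal ≈ 1, mean
off-diagonal ≈ 0. That is the structure that carries within-family
information; the pedigree value of 0.5 for full sibs refers to a founder
base population that single-family marker data cannot express. Centering
at the theoretical segregation frequency ½ is available
(`center="expected"`).

REML for y = 1μ + u + ε maximizes the restricted likelihood profiled
down to λ = σ²ᵤ/σ²ₑ on the eigenbasis of **A** (bounded search over
log λ ∈ [−10, 10], tolerance 1e−6), with BLUPs from the mixed-model
equations at the optimum; the optimizer is cross-checked against a
10,000-point grid search on small fixtures. h² = σ²ᵤ/(σ²ᵤ + σ²ₑ) on the
genotype-mean scale. Missing phenotypes are dropped casewise; each
trait-year is fitted separately (no multi-year model). Note that for
sparse architectures (one large QTL) the GRM-based h² is conservative;
recovery is unbiased within ±0.1 when the generating model matches
(u ~ N(0, Aσ²ᵤ)), which the tests verify at h² ∈ {0.2, 0.5, 0.8}.

## QTL scanning and model selection

Genotype probabilities: forward–backward HMM per individual and linkage
group on a grid of markers plus pseudomarkers (default step 1 cM);
transitions are the Kronecker square of the per-parent Haldane chain;
emissions give 1 − e to the observed class and e/3 to the rest (default
e = 1e−4), uniform for missing codes and pseudomarkers. Probabilities at
an untyped midpoint agree with brute-force two-locus enumeration to
1e−9.

Haley–Knott regression uses three genotype-probability contrasts (class
ac as reference) plus intercept and any covariates;
LOD = (n/2)·log₁₀(RSS₀/RSS₁) against the covariate-only null. LOD is
invariant to affine transformations of the phenotype. Zero-variance
phenotypes short-circuit to LOD 0.

Permutation thresholds shuffle phenotype rows against genotype rows with
covariates travelling with the phenotype (preserving the trait–covariate
correlation under the genome-wide null); T_m is the type-7 empirical
(1 − α) quantile of the genome-wide maximum LOD (α = 0.05, 1,000
permutations by default; the calibration suites use 200). Permutations
without covariates share one QR factorization per position across all
permuted phenotypes, which is why 200-permutation thresholds cost
milliseconds. Permutations are independent seeded draws, so results are
invariant to how they are distributed across workers.

Stepwise selection is **additive only**: forward steps add the position
maximizing pLOD = LOD(model) − T_m·(#QTL), interleaved with backward
deletion, followed by one round of per-QTL local rescan (±10 cM). The
two-dimensional two-QTL scan and its interaction penalties are a
deliberate reduction and are not implemented. Reported per QTL: drop-one
LOD, per-class effect estimates (mean-centred), drop-one explained
variance 100·(RSS₋q − RSS_full)/TSS, and the 1.5-LOD support interval
(the contiguous run around the peak with LOD within 1.5 of the peak,
expanded one grid point beyond each crossing; one-sided at group ends).
Genome-wide type-I error of the full procedure is calibrated at
0.05 ± 0.02, and a 20%-variance QTL at n = 351 is detected in ≥80% of
replicates with median localization error well under 5 cM.

Collocation groups same-trait QTL on a linkage group across years by
complete-linkage clustering of peak positions with an inclusive 8 cM
threshold; "8 cM" is ambiguous between peak distance and interval
overlap, so an interval-overlap mode is provided behind `mode="interval"`.
The covariate diallel runs stepwise models for every ordered
(trait, covariate) pair per year, reports QTL collocated across all
years, and flags those absent from the univariate results as novel; a
trait used as its own covariate is rejected. No multiple-testing
adjustment is applied across traits or years beyond the per-scan
permutation thresholds.

## Pipeline and reproducibility

`run_pipeline` executes simulate → phenotype → topology → BLUP → scan →
collocate → report from one YAML config with a single seed that fans out
to fixed per-stage offsets, so any stage reruns reproducibly in
isolation. The manifest records the config hash and SHA-256 of every
artifact; identical configs reproduce identical checksums for the
deterministic stages. Two phenotype modes exist: `images` (render scenes,
segment, measure — the full chain) and `tabular` (simulate the seven
trait values directly, for studies of the genetics stages alone). The
demo configuration (48 genotypes, two 60 cM groups, 25 fruit per scene at
3 px/mm, 200 permutations) runs the images mode end to end in about half
a minute on one CPU; test suites use smaller panels chosen to keep the
whole suite under a minute of simulation time while leaving Monte-Carlo
error comfortably inside the asserted tolerances. Reporting produces
per-trait-year h² tables, the BLUP trait-correlation matrix, and linear
per-linkage-group LOD tracks with support intervals (no circular plots).

## Known limitations

* Chord-based length/width through the centroid differs from Feret
  diameters for strongly asymmetric fruit; the convention is deliberate.
* The contour density mode carries rasterization anisotropy of a few
  percent at equal radius; the foreground mode is smooth (<1%).
* Scanning BLUPs of a trait whose polygenic background is built from the
  map's own markers denoises the genetic signal and can reveal many true
  small loci on a short synthetic genome; this is a property of the
  generator, not an artifact of the scan.
* Touching fruit, lighting gradients, color, and occlusions are not
  modelled; no interaction (epistasis) scans; the linkage map is taken
  as given.
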