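# Methods

This note documents the models, conventions and design choices behind
`punctascreen`, in the order the pipeline runs.

## Synthetic screen model

The generator emulates a confocal localization screen of yeast-sized
cells expressing a punctate organelle marker.

**Geometry.** Cells are non-overlapping ellipses with axis lengths drawn
uniformly from 40–70 px (at the default 1024 px field), random
orientation, placed by rejection sampling with conservative
bounding-circle overlap checks; at high densities fewer cells than
requested may fit, and the ground truth records what was actually placed.
Puncta are isotropic 2D Gaussian spots (scale = "radius", truncated at
three radii) placed uniformly inside a parent cell. Per-cell punctum
counts are Poisson with mean `puncta_rate`, or fixed via
`puncta_per_cell` when an exact planted count is needed; a minimum
center-to-center separation can be enforced for segmentation oracles
(the generator raises rather than silently under-placing a fixed count).

**Optics and noise.** Each punctum has an axial position; its in-plane
amplitude per optical section falls off as a Gaussian in z (sd = 1 slice).
A fraction `diffuse_fraction` of each cell's integrated punctate signal
is re-rendered as uniform cytosolic haze. Planes are blurred with a
Gaussian PSF (`psf_sigma_px`, default 1 px), then Poisson noise is applied
to the signal, a constant background pedestal is added, and zero-mean
Gaussian read noise is superimposed (clipped at 0). Treating the
background as a noise-free detector pedestal makes the expectation of a
noisy render equal the noise-free render exactly, which the test suite
exploits; it slightly understates background shot noise relative to a
real detector. Geometry and noise use separate RNG streams so replicate
renders of one field under fresh noise are possible.

**Acquisition defaults** are 7 optical sections, 1 µm step, 1024 × 1024 px
— the stack geometry of the screen this pipeline targets. Per-field cell
density is not documented for such screens; the default of 60
cells/field is a convention chosen to give order-10² segmented puncta per
wild-type field, comfortably inside the QC window.

**Phenotype classes.** Reference and inlier wells share the wild-type
phenotype (λ ≈ 2 puncta/cell, peak ≈ 400 counts over a 100-count
background). Class A ("more diffused") uses λ ≈ 12 at 40% peak intensity
with 25% diffuse haze; class B ("sparser but more intense") uses λ ≈ 0.7
at 250% peak and 160% radius. The direction of these shifts matches the
two aberrant pattern families such screens report; the magnitudes are
free parameters of the simulator.

**Profile-matrix surrogate.** For statistical-stage testing at screen
scale, `generate_profile_matrix` skips rendering: features are
independent Gaussians (mean 1.0, sd 0.1) and each outlier class receives
configured mean shifts on named catalogue features (defaults: class A
raises count-type features ≈ +5 sd and lowers per-object intensity
≈ −4 sd; class B the opposite, plus larger object size — every class
shifts ≥ 10 features by ≥ 4 sd). Independence across features is a
deliberate simplification: real morphological features are strongly
correlated, so passing recovery tests on the surrogate demonstrates the
ranking machinery, not performance on real screens.

## Profiling

Projection is the pixelwise maximum over z. Segmentation is deterministic:
Gaussian smoothing (sd 1 px) → global Otsu threshold on the smoothed
projection → hole filling → 8-connected components → discard objects
smaller than 3 px. Because Otsu's split is computed on the image's own
histogram, segmentation is invariant to constant intensity offsets and to
linear intensity scaling; a constant image yields zero objects.

Each object contributes 19 measurements: area, perimeter, equivalent
diameter, major/minor axis lengths, eccentricity, solidity, extent, form
factor (4π·area/perimeter², defined as 1.0 for degenerate zero-perimeter
objects), aspect ratio (major/minor, 1.0 when the minor axis is 0), and
nine intensity statistics (integrated, mean, median, sd, MAD, min, max,
lower/upper quartile) over the raw projected values in the object mask.
Conventions fixed for bit-stable tests: 0-based pixel-centered
coordinates, unscaled median absolute deviation, linearly interpolated
quantiles, population sd (ddof 0, so a single object has sd 0).

A profile is the 19 measurements each summarized by
{mean, median, sd, MAD, min, max, IQR} (133 features) plus 12 image-level
features (object count, log10(count+1), total object area, foreground
area fraction, mean foreground/background intensity, their contrast
ratio, total integrated intensity, mean and sd of nearest-neighbor
centroid distance, whole-image sd and 99th percentile): 145 features in a
frozen order (`punctascreen.catalogue`, version 1.0). A field with zero
objects yields an invalid all-NaN profile rather than imputed values; QC
removes it regardless. The QC filter retains profiles with object counts
in the closed interval [50, 1000]. One profile is computed per field;
aggregation of multiple fields per strain is left to the caller.

## Preprocessing

Stages run in this order: variance filter → unit-norm scaling → range
filter → reference subtraction, so the 0.01 range cutoff applies to
*normalized* values. "Low variance" is implemented as variance ≤ 1e-12
(effectively constant columns) because the subsequent range filter already
removes near-constant normalized features; the tolerance is exposed in
`PreprocessConfig`. Normalization pools all rows (all plates) when
computing each column's Euclidean norm; a per-plate variant exists behind
`per_plate_norm` for sensitivity analysis but is not the default.
Boundary semantics are strict and tested: variance ≤ tol removed; range
< 0.01 removed (exactly 0.01 retained). Reference rows are centered along
with everything else, so their mean difference profile is the zero
vector. Each stage records dropped features with reasons; a stage that
would remove every feature raises instead.

## Outlier screening

A one-class SVM (ν-parameterization) is fitted to **all** difference
profiles, references included — references can legitimately be flagged,
and their flag rate is itself a quality readout. Defaults: RBF kernel,
ν = 0.10 (matching the top-10% flagging convention), and kernel width

    gamma = 1 / (n_features × total variance),

where *total variance* is the trace of the feature covariance (the sum of
per-feature variances). This wide-kernel rule makes the decision function
nearly linear in the data's own units, so the score ranking agrees with a
centroid-distance oracle on radially symmetric clouds; the narrower
mean-per-feature-variance rule (scikit-learn's `'scale'`) wraps the
boundary around dense planted outlier clusters at screen scale and fails
planted-recovery, so it is available in config but not the default.

The outlyingness score is −f(x); larger means farther outside. Ranks are
1..n by descending score with ties broken by strain id, making the table
deterministic and row-order invariant. The flagged set is the top
⌈fraction·n⌉ ranks (fraction default 0.10).

**First-kink cutoff.** The descending flagged-score sequence is smoothed
with a centered moving average (window 5); absolute second differences of
the smoothed curve are compared against 3× their median plus a tiny
absolute floor (10⁻¹² of the score range, so exactly-linear sequences
report no kink); the first contiguous run of exceedances marks the kink
region, and the cutoff is the peak of the *unsmoothed* second differences
within that region. Detection on the smoothed curve gives robustness to
score noise; localization on the raw curve returns a clean
piecewise-linear vertex exactly. Edge-affected indices (within half a
window of either end) are excluded. Fewer than 5 scores: no cutoff, full
set returned with a warning. Window and multiplier are configurable.

**Quality.** Pollution = (flagged references)/(flagged total); the
complementary reference flag rate (flagged references / all references)
is reported alongside. Mutant and reference score distributions are
compared with the two-sided two-sample Kolmogorov–Smirnov test
(`scipy.stats.ks_2samp`, exact method for small samples — verified in
tests against exhaustive permutation enumeration).

## Clustering, characterization, enrichment

Flagged strains are clustered by complete-linkage agglomeration on
Euclidean distances (scipy linkage; verified against a naive O(n³)
oracle). Cutting the tree with `cut_tree` yields exactly k groups and
successive cuts are nested refinements; the subgroup count for
second-round clustering is a parameter, not model-selected. Groups are
characterized per feature by the two-sample KS statistic against inlying
strains, with shift direction = sign(group median − inlier median), ranked
by D with name tie-breaks. Enrichment uses the one-sided upper-tail
hypergeometric p-value per term (verified against exact combinatorial
tail sums) with Benjamini–Hochberg adjustment across terms; the
background defaults to all screened genes, and annotation tables are
plain gene↔term inputs, so tests use synthetic annotations.

## Co-localization

Foci are detected per channel with multi-scale Laplacian-of-Gaussian blob
detection on min-max-normalized projections (offset- and
scale-invariant); each focus is assigned to the cell mask containing its
centroid (masks come from synthetic truth or upstream segmentation), and
foci outside every cell are excluded from per-cell means. A green focus
counts as apparently co-localized when its nearest red focus lies within
`d_c` (default 3 px at the synthetic pixel scale — a free parameter; no
physical contact distance is implied). Strain comparisons use a pooled
two-proportion z test for co-localized fractions and a two-sided Wilcoxon
rank-sum test for per-cell counts; both conventions are defaults, not
inferences. The synthetic two-channel field plants an exact co-localized
fraction: each co-localized green focus is placed within d_c/4 of its own
host red focus (hosts drawn without replacement; extra host reds are
planted when the Poisson draw falls short, so high planted fractions need
enough cells for the red rate to dominate), and non-co-localized greens
are kept ≥ 3·d_c from every red focus. Same-channel foci keep a minimum
mutual separation so detection resolves them individually.

## Problem sizes and tolerances in the shipped tests

The acceptance suite runs ten replicate 1000-strain surrogate screens for
planted recovery (recall ≥ 0.9, pollution ≤ 0.05), fifty 500-strain
all-null screens for calibration (mean pollution within 3 binomial sd of
the 20% reference proportion; KS p-values uniform at α = 0.01), a
thousand random n ≤ 8 instances for the linkage oracle, exhaustive KS
permutation enumeration at n,m ≤ 6, and fifty replicate co-localization
fields per planted fraction (15%, 30%; recovery within the 95% binomial
interval). Image-based tests use 256–512 px fields with tens of planted
puncta; one default-geometry 1024 px field verifies the acquisition
contract. These sizes keep the full suite under a minute while leaving
every statistical check adequately powered.

## Known limitations

- The simulator renders whole fields, not brightfield channels, no 3D
  PSF, no illumination gradients or plate-position effects; the profile
  surrogate ignores feature correlations. Passing tests demonstrate the
  pipeline's statistical machinery under its stated assumptions, not
  performance on real micrographs.
- The 145-feature catalogue is this package's own construction (19 × 7 +
  12); real CellProfiler feature lists differ in detail, so absolute
  feature values are not comparable across tools.
- The number of features surviving preprocessing is data-dependent and is
  reported per run, not contracted.
- Batch-effect correction, imputation and deconvolution are out of scope.
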