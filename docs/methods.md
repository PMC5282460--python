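# Methods

## The measurement model

The pipeline treats a multispectral microscopy stack as a 3-D image: two
spatial axes and the wavelength axis (16 bands spanning 500–650 nm, in page
order of the TIFF). Texture is quantified by second-order statistics — how
often two gray levels co-occur at a fixed spatial displacement — under the
assumption that the *spatial–spectral* arrangement of intensities inside the
cell, not its mean brightness or shape, carries the grading signal. All
displacement geometry uses one fixed convention: `x` = column, `y` = row,
`z` = band, 0-based, origin top-left.

### Co-occurrence matrices

For a quantized volume `L` and translation vector `t = d·u`, the matrix
entry `(i, j)` counts ordered voxel pairs `(p, p + t)` with `L(p) = i`,
`L(p + t) = j`, where **both** endpoints lie inside the image and inside the
2-D cell mask (applied at every band). In 3-D, one representative of each ±
pair of the 26-neighborhood suffices — 13 unit directions — because the
matrix of `−t` is exactly the transpose of the matrix of `t` (a property
tested directly). Directions are never pooled or symmetrized: each of the
13 directions keeps its own matrix, which is what makes the grouped feature
counts 12 × 13 × |offsets| come out at 156 and 624.

Texture functions are evaluated on the *normalized* matrix (entries sum to
1). Raw counts are retained for provenance, and a displacement that yields
zero valid pairs is flagged as an empty matrix and refused by the feature
stage rather than silently zero-filled — an offset of 8 along the band axis
of an 8-band volume is an error the user should see.

### The 12 texture functions

Gray levels are indexed 1…Ng in every moment formula (so the sum-mean's
index `i + j` starts at 2). Energy is `Σ p²`; the occasionally-seen variant
with an `i·j` weight contradicts both the verbal description ("high when few
entries dominate") and the magnitude of typical reported values, so the
plain squared-probability form is used. The sum-mean constrains its inner
sum to the anti-diagonal `i + j = n` (without that constraint the expression
degenerates to an Ng-fold multiple of the total probability). Contrast and
inertia are the same functional written two ways, as are homogeneity and the
inverse difference moment; both aliases are computed so feature vectors keep
the conventional 12-function layout, and the identities are asserted in the
tests via an independent literal transcription. Entropy uses the natural
logarithm (configurable). When a marginal is degenerate (σx·σy = 0) the
correlation is reported as 0 with an explicit flag instead of dividing by
zero.

### Quantization

Cells are mean-filtered (3 × 3 by default; the smallest standard kernel,
configurable) and histogram-equalized to Ng = 32 levels using the inclusive
empirical CDF of the within-mask intensities: `level(v) =
min(⌊Ng·CDF(v)⌋, Ng−1)`. The CDF is pooled over all bands of one cell by
default so that a given level means the same thing along the spectral axis —
necessary for 3-D pairs to be interpretable; a per-band mode exists for
comparison. The mapping is monotone and invariant to strictly monotone
intensity transforms (both property-tested). Out-of-mask pixels get level 0
but never enter any pair count.

### Segmentation

A two-region piecewise-constant (Chan–Vese) active contour is run on the
band-mean image after smoothing, at a 64 × 64 working resolution, from a
centered disk initialization, with curvature weight μ = 0.1, tolerance 1e-3
on the level-set change and a 200-iteration cap. Only the resulting contour
is upscaled (nearest-neighbour) to full resolution. The cell is taken to be
the region occupying the smaller share of the image border (a compact
interior object), reduced to its largest connected component. Degenerate
inputs (zero-variance image) and empty results raise distinct errors.

Overlap scoring uses the union-normalized family
`JSC = |A∩B|/|A∪B|`, `FPR = |B∖A|/|A∪B|`, `FNR = |A∖B|/|A∪B|` — the unique
definitions under which `JSC = 1 − FPR − FNR` holds as an exact identity —
together with the standard Dice coefficient `2|A∩B|/(|A|+|B|)`.

### Selection and classification

Features are z-scored with the sample-SD convention (ddof = 1; the column
`[1,2,3]` maps to `[−1,0,1]`). Zero-variance columns are dropped with a
warning. A one-way fixed-effects ANOVA F-test per feature keeps `p < 0.01`
(strict, no multiple-testing correction by default; an optional
Benjamini–Hochberg mode is deliberately out of scope here). PCA on the
selected z-scored features retains the smallest component count reaching
97% cumulative explained variance; each component's sign is fixed by making
its largest-magnitude loading positive, so scores are reproducible and
invariant to feature-column permutation.

Leave-one-out cross-validation refits the *entire* preparation chain
(z-score → ANOVA → PCA) inside every fold by default, so feature selection
never sees the held-out sample; a `refit_selection=False` "paper mode" fits
the chain once on all samples, reproducing the common protocol in which
selection precedes cross-validation. If no feature clears α in a fold (a
real possibility under label permutation), the single smallest-p feature is
kept so the fold still produces a prediction; the condition is flagged.

Classifiers: CART with Gini criterion (scikit-learn, `random_state=0` for
deterministic tie-breaking), Gaussian naïve Bayes, and 1-NN with Euclidean
distance. ROC scores for the pairwise AUCs are class probabilities for the
tree and naïve Bayes and the negative distance to the nearest same-class
training sample for 1-NN; ties get the mid-rank (trapezoidal) treatment.
Percentages in reports are truncated — not rounded — to two decimals
(`18/19 → 94.73%`), the display convention of the reference tables the
one-vs-rest worked examples reproduce; raw fractions are always retained.

## The synthetic phantoms

The generator emulates the study conditions: 27 volumes (9 per class) of
16 bands at 512 × 512 × 8-bit, one cell per volume. Inside the cell the
texture is a Gaussian random field (Gaussian-smoothed white noise,
renormalized to unit SD) with per-class parameters:

| class | correlation length (px) | contrast amplitude (gray levels) |
|-------|------------------------|----------------------------------|
| BH    | 8                      | 20                               |
| IN    | 4                      | 35                               |
| Ca    | 2                      | 50                               |

This is the simplest field with a tunable correlation length, and the
parameter ordering reproduces the qualitative texture ordering of the
lesion continuum: after equalization the GLCM of a long-correlation cell
concentrates near the diagonal (low entropy, high energy — BH), while a
short-correlation, high-contrast cell spreads it out (Ca). Bands share half
their field variance (one common low-frequency component), emulating
spectral redundancy. Patient-to-patient variability is a log-normal jitter
(15% by default) on both texture parameters — the real intra-class spread is
unknown, so it is exposed as a parameter rather than asserted. The cell
boundary is a smooth random-star polygon (radial harmonics 2–5 on a circle
of radius 0.3 × image size, with center jitter) so the active contour is
exercised on a non-circular shape; the background is a brighter tilted plane
(mean 190 vs. cell mean 120) with faint large-scale structure and a 1.5
gray-level noise floor. One integer seed drives a single RNG stream per
sample; cohort sample `i` uses `base_seed + i`. Identical specs are
bit-identical.

What the phantoms deliberately do **not** emulate: H&E staining appearance,
chromatin/nucleus substructure, wavelength-dependent absorption physics,
multiple touching cells, or imaging artifacts. Passing the pipeline on
phantoms therefore demonstrates that the machinery measures and separates
the *kind* of texture differences the classes are defined by — not that the
specific published accuracies on real tissue are reproduced, which would
require the original images.

## Problem sizes and numerical tolerances

The unit suite exercises feature extraction on a 27-sample cohort at
96 × 96 × 16 (same class structure, smaller spatial size); the end-to-end
recovery check and the acceptance script use the full default conditions
(512 × 512 × 16, 27 samples) with base seeds 1/102/203 tried in turn until
the 85% LOOCV accuracy bar is met. GLCM counting is verified against a
brute-force pair enumeration on random masked volumes up to 8 × 8 × 3, and
the texture functions against a literal term-by-term transcription at
1e-10. Statistical behavior is checked by simulation: the ANOVA filter's
type-I error at α = 0.01 must sit inside the 99% binomial band over 200
null replicates of 100 features × 27 samples; a planted effect with class
means (0, 3, 6) and unit noise must be detected with power > 0.99 over 500
replicates; and label-permuted LOOCV accuracy must sit at the 1/3 chance
level over 200 permutations, with a 0.05 allowance below chance for the
known pessimistic bias of leave-one-out on permuted labels (the held-out
sample's class is underrepresented in its training fold).

## Known limitations

* The equalization scope (pooled across bands) and the exact active-contour
  initialization/stopping rule are documented package choices; other
  implementations of the same pipeline may differ in these unspecified
  corners.
* At 9 samples per class, LOOCV accuracy is a coarse statistic (1 sample =
  3.7 points); seed-to-seed variation of a few samples is expected and is
  why the recovery experiment documents three base seeds.
* The feature-correlation utility requires balanced classes (it aligns
  per-class sample blocks).
* 2-D GLCM geometry is provided (4 directions per slice) but the pipeline's
  feature groups are exclusively volumetric, matching the design being
  implemented.
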