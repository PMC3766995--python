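# Methods

## Pipeline model

An AFM height map is a rectangular grid of surface heights.  The
analysis assumes that (i) absolute heights carry no grading
information — only spatial structure does — and (ii) the texture of
interest is bright raised structure (neuropil fibres, nuclei) against
dark depressions (cavities).  Accordingly:

1. **Flattening.**  The background slope (sample tilt) is removed by
   subtracting an ordinary least-squares plane `z = a + b·col + c·row`
   fitted over all pixels.  The residual grid has zero mean and the
   operation is exactly invariant to adding any plane.  A per-scan-row
   first-order fit (`mode="line"`) is available for data with
   line-wise drift; the global plane is the default because it is the
   minimal first-order correction and does not introduce row-seam
   artifacts.

2. **Equalization.**  Heights are mapped to gray levels
   `g(v) = min(floor(256·C(v)/N), 255)` where `C(v)` is the number of
   pixels with height ≤ v.  This is a pure rank transform: monotone,
   invariant to any monotone rescaling of heights, and it spreads any
   height distribution over the full 256-level range.  Conventions
   fixed for bit-exact reproducibility: ties share a level, a constant
   image maps to 255, ranking uses full numeric precision.  Under this
   floor convention a perfectly uniform rank image is flat to ±1 pixel
   per level (the clip at 255 moves one rank's worth of pixels from
   the bottom to the top level).

3. **Level sets and functionals.**  At threshold t ∈ {0,…,255} a pixel
   is foreground iff its level ≥ t, so cavities become background and
   drive hole formation.  Per level set:
   * area = foreground pixel count;
   * contour length = number of unit pixel edges between foreground
     and background, the exterior counting as background (border
     foreground contributes its outward edges; no Crofton correction —
     lengths are in pixel-edge units);
   * Euler characteristic = 8-connected foreground components minus
     4-connected background components not connected to the exterior.
     Computed by quad counting on the padded mask,
     χ = (Q₁ − Q₃ − 2·Q_D)/4, which equals the labeling definition on
     every input (verified exhaustively on all 512 3×3 images and on
     random masks against a two-pass labeling oracle).

   The full 256-level curves are evaluated in a single pass: every
   pixel pair and pixel quad changes its contribution at known
   thresholds, so per-level counts accumulate as range histograms
   (O(pixels) total rather than O(256·pixels)).  The connectivity pair
   (foreground 8, background 4) and the foreground-above-threshold
   orientation are fixed, not configurable, so results are bit-exact.

## Curve descriptors

Each sample is reduced to 15 scalars: from the Euler curve the
min/argmin, max/argmax, first zero-crossing after the argmin
(saturating to 255 when the curve never returns to ≥ 0), the maximum
forward-difference slope between argmin and argmax and its position,
and the negative/positive/signed areas; from the contour curve the
max/argmax, FWHM (number of levels at ≥ half maximum), total area and
centroid.  Ties in extrema resolve to the lowest gray level.  The
slope is measured after a moving-average smoothing of width 5 levels
(configurable); unsmoothed forward differences on an integer curve are
dominated by single-level noise.  Identically-zero curves map to
all-zero descriptors, so a featureless sample sits at the origin of
feature space (this overrides the literal zero-crossing and FWHM rules
in the degenerate case, which would otherwise return arbitrary small
positives).

## Group statistics

Per-grade curves are summarised by the per-level arithmetic mean and
the sample standard deviation (n−1).  The "1σ band" is mean ± 1 sd — a
dispersion band, deliberately not a standard error, because its
purpose is to find gray-level windows where the two groups' typical
curves do not mix.  Extreme-value ratios divide like-signed extremes of
the two mean curves (grade II over grade IV), reported signed and
rounded to two decimals.  Non-overlap bands are the maximal contiguous
windows where the two intervals are disjoint; the band feature is the
mean Euler value over a window, classified by a one-dimensional
threshold rule whose cut and orientation are fitted per training fold.

## GP classifier

Strongly-typed expression trees: Boolean root (true ⇒ grade IV),
logical operators AND/OR/NOT/XOR, comparisons </≤/>/≥ over real
subexpressions, arithmetic +, −, ×, and protected ÷ (returns 1 on a
zero divisor), leaves are feature references or constants drawn
uniformly from a randomly chosen feature's training range.  Trees are
built well-typed and never repaired at evaluation.

Evolution: generational, population 70, tournament selection (size 2),
subtree crossover between type-compatible points with probability 0.9,
elitism 1, and with the configured mutation probability one of four
mutators chosen uniformly — replace branch, change node type (swap an
operator within its arity/type class or redraw a leaf), full tree
shaker (re-randomize all constants), one point shaker (re-randomize
one constant).  Offspring violating the depth or node-count limits are
discarded and the first parent retained, so limits hold for every
individual of every generation.  Fitness is raw training accuracy;
the run stops early when a tree classifies its training set perfectly,
since with accuracy fitness and elitism further generations cannot
improve the best-of-run.  Tournament size, crossover probability and
elitism are not part of the published parameter grid; the defaults
above are common GP practice and configurable.

Evaluation: stratified k-fold cross-validation (default 10 folds),
repeated n_runs times (default 10) with seeds derived from one root
seed; the headline number is the best run's mean test accuracy, with
mean ± sd across runs reported alongside.  When the number of folds
equals the sample count the folds degenerate to leave-one-out
(singleton, unstratified test folds).  The grid search covers the
2·2·2·3 = 24 combinations of generations {70, 100}, mutation
probability {10, 15}%, tree depth {8, 10} and tree length
{25, 50, 80}, ranked by best-run accuracy.  All randomness flows from
a single seed; repeated invocation is bit-identical, and fold models
depend only on their training portion (asserted by a
label-poisoning test).

## Synthetic textures

The generator composes, on a tilted plane: fibres as persistent
random-walk ridges (heading diffuses with sd 0.15 rad/step, walk
length ~ image edge, Gaussian-smoothed to the target thickness),
nuclei as Gaussian bumps, cavities as depressions with
Fourier-perturbed polar outlines, plus i.i.d. Gaussian pixel noise
(sd 0.12 against structure heights of 0.6–2).  Grade II defaults
(native 512×512): 70 fibres, 30 nuclei (radius 5–10 px), 12 small
cavities (5–12 px).  Grade IV: 12 fibres, 6 nuclei, 16 large irregular
cavities (20–50 px).  Counts scale with image area (floored at one
structure per native kind) and radii with edge length, so smaller
images preserve the class geometry.  Dataset generation jitters counts
and radii by ±20% per image and derives per-image seeds from one root
seed.  Default cohort size is 54 + 59.

The generator's contract is qualitative: sigmoid Euler curves,
parabola-like contour curves, and the between-grade ordering (grade II
has the deeper Euler minimum and the larger contour maximum).  It is
not calibrated to clinical magnitudes — synthetic Euler minima at
256×256 are on the order of −10³ and carry no claim about real tissue
— and it omits AFM tip convolution, scan-line noise and staining
effects.  A pipeline that passes on these textures is shown to have
working discriminative machinery, not clinical validity.

One empirically relevant subtlety: after rank equalization, i.i.d.
pixel noise becomes dense salt-and-pepper speckle whose Euler dip is
*deeper* than that of correlated texture, so "more negative χ
minimum" discriminates between the two structured classes but does not
separate structure from pure noise.

## Problem sizes and numerical choices

The packaged end-to-end classification check runs 54 + 59 synthetic
images at 256×256 with one grid configuration (70 generations,
mutation 15%, depth ≤ 8, length ≤ 25), 10 runs × 10-fold CV — chosen
as the smallest cohort that exercises every stage at full statistical
structure while keeping a complete run in the low minutes on one core.
Degenerate conventions: empty band → error; zero denominator in an
extreme ratio → undefined-ratio flag; all-zero curves → all-zero
features; plane fits use `numpy.linalg.lstsq` with its default rcond.

## Known limitations

* Contour length is an edge count; it overestimates the geometric
  perimeter of diagonal boundaries by up to √2 (consistent with
  reporting curve magnitudes in "pixel" units).
* The 15-descriptor list is this package's fixed definition of the
  curve-shape feature family (extrema, zero-crossing, steepness,
  areas); output headers carry the names so any substitution is
  traceable.
* Exact flatness of the equalized histogram is ±1 pixel per level, a
  consequence of the floor-plus-clip mapping.
* GP results, while seeded and reproducible, are stochastic across
  seeds; accuracy claims should always cite the repeated-CV summary,
  not a single run.
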