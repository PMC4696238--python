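# Methods

This note documents the models and procedures `flgrade` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
establish.

## Saturation and registration

All detection-side image analysis runs on the HSV saturation channel,
S = (max−min)/max with S = 0 at black, computed per pixel from 8-bit RGB.
Saturation separates follicle tissue, non-follicle tissue and white slide
background far better on a CD20 immunostain than any single H&E channel,
and it is invariant to overall brightness.

Grading happens on H&E, so the CD20 image is mapped onto the H&E pixel
grid by a rigid transform (translation + rotation about the grid center,
optional uniform scale; `theta` in radians, positive counter-clockwise in
(row, col) axes). Estimation is intensity-based and coarse-to-fine: mean
pooling builds a pyramid whose apex has a longest side of ~96 px; at each
level a rotation sweep (steps 1°, 0.5°, 0.25°, 0.1° from coarse to fine,
initial range ±5°) is combined with FFT phase correlation for the
translation, and every candidate is scored by zero-mean normalized
cross-correlation (NCC) of the full-resolution saturation maps. A candidate
is accepted only if it does not lower that score, which makes the per-level
score sequence non-decreasing by construction, and the identity transform
is always among the candidates, so the returned transform never scores
below it. Degenerate (constant-saturation) inputs and candidate transforms
with under 25 % overlap are rejected as errors rather than guessed at.

Warping is bilinear per RGB channel with white (255,255,255) fill, the
color of bare slide glass. On same-source pairs the estimator recovers
translations to under a pixel and rotations to under 0.1°; on cross-stain
pairs (synthetic H&E vs CD20, which share only coarse follicle structure)
accuracy is a few pixels — immaterial against 1365 × 2165 px detection
blocks.

## HPF detection

Defaults are the 40× operating point: HPF blocks of 1365 rows × 2165
columns (0.159 mm² at 0.23 µm/px), local thresholding windows of
400 × 400 px, positivity cut 0.75 (strict: a block at exactly 75 % is
rejected), histogram of 100 bins on [0, 1], fallback threshold 0.5.

The threshold is chosen per slide: the mean saturation of every local
window is histogrammed and the center of the unique maximal bin is the
threshold. Ties for the maximum, or all mass in a single bin touching a
domain boundary, count as "no peak" and fall back to 0.5. Whether the
histogram should be built from window means or raw pixels, and per slide or
per block, is not uniquely determined by the rule's verbal description;
per-slide window means is the simplest reading and is fixed here as a
convention. Note the mechanism's reach: it assumes the modal windows are
background (or at least that the modal bin's *center* sits above the
background cluster), which holds for background that is tightly clustered
within one bin but is not guaranteed for arbitrary slides — the 0.5
fallback and a user-supplied threshold remain available.

Every pixel of a window inherits the window's label (mean ≥ threshold).
Blocks are tiled from (0, 0); partial edge blocks and windows are judged
against their own pixel count so thin tissue margins are not penalized.

**Reduced-resolution pathway.** The slide is mean-pooled by an integer
factor (80 maps 40× to 0.5×; an HPF becomes ≈ 17 × 27 px and the window
5 × 5 px) before the same pipeline runs. Block boundaries at reduced scale
are fractional — block *b* starts at round(b·1365/80) pooled rows — so the
reduced grid stays aligned with the level-0 HPF grid; a fixed integer tile
of 17 px would drift off the true block grid by one pooled pixel every ~16
blocks and emit spurious sliver blocks at slide edges (the pooled array
also carries replication-padded edge rows, so the block count is always
derived from the true slide extent, not the padded array). Candidate
bounding boxes are reported in level-0 pixels on the exact block grid.

## Sub-block classification and grading

Each sub-block's feature is the canonical 64-bin color histogram: the RGB
cube split 4 × 4 × 4 uniformly, bin index 16·⌊R/64⌋ + 4·⌊G/64⌋ + ⌊B/64⌋,
counts normalized to sum to one. The kNN rule uses Euclidean distance on
these 64-vectors, k = 49, with ties at the k-th distance broken by
ascending training index (a stable sort realizes this); a sub-block is CB
if at least ⌈k/2⌉ = 25 of its k neighbors are CB. The production-scale
training corpus in the intended workflow is thousands of blocks per class;
`build_training_set` extracts one CB feature per annotation whose centered
64 × 64 box fits its image and samples a fixed number of non-CB blocks per
image (default 20), uniformly among positions whose center is at least
128 px (two block widths — the only length scale available to interpret
"twice the distance") from every marked CB, by seeded rejection sampling
capped at 10,000 attempts.

HPFs are tiled from their own origin; partial edge tiles are discarded,
giving ⌊1365/64⌋·⌊2165/64⌋ = 693 tiles per full field. The rule hierarchy
is: HPF high iff CB tiles > p = 115 (strict); tissue high iff ≥ 50 % of
detected HPFs are high (the inclusive reading; no case in the packaged
table sits on the boundary, so the printed grades are invariant to it). k
and p are configuration inputs, not fitted here. The WHO manual-count
grade uses mean m over ten fields: I iff m ≤ 5, II iff 5 < m ≤ 15, III iff
m > 15 ("more than 15" anchors the top boundary; the other follows by
symmetry for non-integer means).

## Reader-study statistics

Scores are 0–100 confidences that a case is high grade; the dichotomization
cut is 50, inclusive (score = 50 reads as high). Percent agreement is the
fraction of readings whose dichotomized call matches the case truth.

The empirical AUC is the trapezoidal-rule area under the empirical ROC,
computed as the Mann–Whitney statistic (ties count half) via mid-ranks.
Two 95 % intervals are provided:

* **Exact binomial.** The AUC is treated as a binomial proportion with
  N = n_pos·n_neg trials (the number of case pairs under the Mann–Whitney
  view — the natural trial count, though other choices of N are defensible)
  and round(AUC·N) successes; the interval is Clopper–Pearson from beta
  quantiles.
* **Logit / U-statistic.** The DeLong-type variance from placement values
  (sample variances of per-case placements, ddof = 1), carried to the logit
  scale by the delta method, a normal interval there, and inverse-logit
  back. This keeps endpoints inside (0, 1); it is undefined at AUC ∈ {0,1}.

**OR/Hillis comparison.** Per reader × modality accuracy indices (AUC or
proportion agreement) enter the Obuchowski–Rockett model: fixed modality,
random reader, correlated errors. The three error covariances (Cov1: same
reader, different modality; Cov2: different reader, same modality; Cov3:
different both) are estimated by delete-one-case jackknife of the index —
one mechanism for both indices, which is what makes the agreement analysis
possible at all. The modality F statistic is
MS(T) / [MS(T×R) + r·max(Cov2 − Cov3, 0)] with the Hillis denominator
degrees of freedom ddf = (t−1)(r−1)·[denominator]² / MS(T×R)²; the CI for
the mean difference uses the same ddf with standard error
√(2/r · denominator). Negative Cov2 − Cov3 is floored at zero, the standard
practice. The fully degenerate case (identical indices everywhere, 0/0)
returns F = 0, p = 1. Tests are two-sided at α = 0.05, unadjusted.

**ROC averaging.** Reader ROC curves are averaged along the direction of
the (0,1)–(1,0) diagonal: rotating ROC space 45° makes the chance line the
abscissa and every monotone ROC a single-valued function of position along
it (each ROC segment has rotated slope in [−1, 1]); offsets are linearly
interpolated on a 101-point grid, averaged, rotated back, clipped to the
unit square and made monotone by cumulative maximum (the last two steps are
safeguards; for valid inputs the average is already monotone and inside the
square).

## Synthetic data: what it emulates and what it does not

`simulate_slide` plants block-aligned follicles on a 3 × 3 HPF-block slide
(4095 × 6495 px). The CD20 rendering has saturation 0.7 inside follicles
and 0.3 outside plus Gaussian noise (sd 0.05), drawn at a fixed DAB-like
hue so the rendered pixel's saturation equals the field up to 8-bit
quantization. The pseudo-H&E tiles follicle blocks from two palettes — CB
(100, 60, 140) and non-CB (210, 160, 200), ≥ 60 intensity gap per channel —
at CB-tile fractions 0.30 (high-grade follicles: 208 of 693 tiles > 115)
and 0.05 (low: 35 of 693), with per-pixel noise. Palette tiles are anchored
at each block's own origin, the grid a downstream classifier of that block
uses. These values are stand-ins giving clear class structure, not
estimates of real stain statistics, and the slide size balances realism
against single-CPU runtimes; generators are pure functions of their seeds.

`simulate_reader_scores` is a Roe–Metz-style crossed model: latent score =
class separation (modality-specific) + reader effect + case effect +
independent error, squashed to [0, 100] by a fixed logistic map (AUC is
invariant to any fixed monotone map). The implied true AUC is
Φ(sep/√(2(σ²_case + σ²_error))); `separation_for_auc` inverts it. Defaults
emulate an 11-reader, 20-case arm with true AUCs ≈ 0.65 / 0.75. Shared
case effects induce the between-reader correlation the OR machinery
exists for; a purely additive reader effect moves agreement but not AUC,
so between-reader AUC heterogeneity beyond sampling noise is not modeled.

Passing the synthetic end-to-end checks therefore shows the pipeline's
logic — thresholding, tiling, voting, aggregation, and the statistics —
is correct under the stated image model. It does not show robustness to
real-stain variability: nuclear morphology, stain variation, uneven
illumination, non-follicular growth patterns, partially filled or
misaligned follicles, and non-rigid tissue deformation between sections
are all outside the generator, and block-level detection inherits the
assumptions above.

## Numerical and degenerate-input conventions

Coordinates are (row, col), 0-based, with half-open boxes [r0, r1) ×
[c0, c1). Saturation is computed in float32 (quantization and rounding
error ≪ 1e-6 per pixel against a float64 HSV reference). Histogram
invariants are enforced at 1e-9. Empty masks, single-class truth,
non-crossed designs, undersized HPFs and unsatisfiable sampling all raise
typed errors with stable codes rather than returning partial results.
Problem sizes in the test suite (20 detection slides, 10 end-to-end
slides, 500 null replicates at 8 readers × 50 cases, 200 recovery
replicates at 12 × 100, 1,000 CI-coverage simulations) were chosen as the
package's own validation conditions.
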