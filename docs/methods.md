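# Methods

This note documents the models and procedures implemented in `tomatoseg`,
the parameters that matter, the numerical conventions, and what the
synthetic-scene tests do and do not demonstrate.

## Chromatic first layer

The per-pixel discriminant is `icp = α·R − β·B − γ·G`, evaluated in real
arithmetic (never clamped to 8-bit: the value is legitimately negative on
green and achromatic pixels, and clamping would corrupt the threshold
comparison). The mask rule is strict: a pixel is target iff
`icp > separation_parameter`; a tie is background. Defaults
`α = 1.00, β = 0.25, γ = 1.00, θ = 10` are the operating point established
from three 200-pixel calibration sample groups (tomato, green vegetation,
other background). Two useful consequences are tested as invariants:
scaling `(α, β, γ, θ)` jointly by any positive constant leaves the mask
unchanged, and raising `θ` can only shrink the foreground.

The calibration helper returns, for a tolerance `t`, the `t`-quantile order
statistic of the tomato-group icp values (minus an optional margin) together
with the non-target leakage above it. Because the mask rule is strict, the
boundary sample itself is excluded by the suggested threshold; the helper
reports the realised miss fraction so the user can judge. The suggestion
never overrides the configured default — the shipped `θ = 10` was a
deliberate loosening to keep fruit regions complete, and an automatic
override would undo that judgment. Group labels in calibration CSVs are
arbitrary; the tomato set is identified as the group with the largest mean
R − G excess rather than by letter, because naming conventions for the
M/N/K groups are not reliable.

## Block features

Blocks are 9×9 px, tiled row-major without overlap; right/bottom edge
blocks keep their true (smaller) extent rather than being padded, so no
invented pixels enter the statistics. Per block the feature vector is
`(R, G, B, H, S, I, Et, En, Cr, Im, Ls)`:

* Colour: channel means, plus H, S, I computed from those means (not the
  mean of per-pixel HSI — "average colour features" at block level, and
  ~80× cheaper). Hue uses the arccos form with the standard `2π − arccos`
  reflection when B > G, reported in radians in [0, 2π); conventions:
  S = 0 for an all-black pixel, H = 0 when the arccos denominator vanishes
  (achromatic). H is divided by 2π so all raw features share comparable
  scales before min–max normalization.
* Texture: grey-level co-occurrence matrix of the block's red channel,
  linearly quantized to `k = 16` levels (256 levels over an 81-pixel block
  would leave the matrix nearly empty; configurable). Offsets are distance 1
  in the four directions 0°, 45°, 90°, 135°, accumulated with their
  opposites into one symmetric matrix normalized to mass 1. From it:
  entropy (base-10 logarithm, configurable; zero cells contribute nothing),
  energy, correlation (defined 0 when a marginal standard deviation
  vanishes, i.e. a constant block), inertia moment and local smoothing,
  with matrix indices running 1..k. A block too small for any pair (1×1
  edge block) degenerates to all mass at its single grey level, which
  yields the constant-block feature limits (Et 0, En 1, Cr 0, Im 0, Ls 1).

Normalization is per-feature min–max fitted on the training table;
prediction-time values outside the training range are clipped to [0, 1].
A feature constant on the training set is flagged and mapped to 0.

## I-RELIEF feature weighting

Weights are estimated by the iterative-RELIEF fixed point: under the current
weighted L1 metric, hit/miss assignment is softened with the kernel
`f(d) = exp(−d/σ)` normalized per sample; each sample's margin contribution
is damped by the probability that it is not an outlier (its normalized
same-class kernel mass); the new weight vector is the positive part of the
expected margin, rescaled to unit L1 norm; iterate until the L2 change
drops below `tol`. Defaults: `σ = 0.5` on [0, 1]-normalized features,
`tol = 1e-4`, `max_iter = 100` — stable convergence on normalized data in
pilot simulations; all configurable. Non-convergence returns the last
iterate with a warning. If the margin has no positive component (possible
only when no feature carries signal) the previous iterate is kept, with a
warning.

Two properties worth stating precisely. On designs with an informative
feature the weight mass concentrates on it (parameter-recovery tests), and
exact duplicate features receive exactly equal weight by symmetry of the
arithmetic. On *pure-noise* designs, however, the expected margin is zero
and the positive-part update can latch onto an arbitrary feature for a
given finite sample; what the algorithm guarantees — and what the tests
assert — is the absence of any systematic preference across seeds, with a
diffuse seed-averaged weight vector. No feature is ever hard-eliminated by
design; a zero weight can only arise from the positive-part update itself.

## Weighted RVM

The second-layer classifier is a sparse Bayesian logistic model over kernel
bases centred on the training blocks plus a bias column. The kernel is the
anisotropic Gaussian `exp(−Σⱼ wⱼ(xⱼ−yⱼ)²/(2·width²))` with the I-RELIEF
weights; with uniform weights it reduces exactly to a plain RBF on
normalized features (verified numerically). Training alternates a
Laplace-approximation fit of the basis coefficients (Newton steps with
backtracking) with the evidence update
`αᵢ ← (1 − αᵢΣᵢᵢ)/μᵢ²` of the per-basis prior precisions, pruning bases
whose precision exceeds `prune_threshold = 1e9`. The bias basis is never
pruned. Convergence is judged on the *well-determined* bases (those with
`1 − αᵢΣᵢᵢ > 1e-3`): poorly-determined bases shrink towards pruning at a
slow geometric rate that would otherwise stall the criterion, and they are
removed at the end regardless since their coefficients are statistically
indistinguishable from zero. On cleanly separable data the evidence
maximisation may legitimately not meet the tolerance within
`max_em_iter = 200`; the last iterate is returned with a warning, and all
quality contracts (accuracy, sparsity, label-swap symmetry) still hold.
Kernel width default 0.5 on normalized features; the model file is a
versioned JSON schema carrying the relevance vectors, coefficients,
precisions, feature weights, normalization statistics and the feature
configuration, so detection cannot silently run with mismatched features.

The target class (label 0 in training tables) is mapped internally to the
positive logistic class, so the reported probability is always
"probability of target"; the decision rule is strictly `p > 0.5`. Blocks
whose features come out non-finite are classified with those features
replaced by 0 after normalization (and logged) instead of crashing.

## Fusion, filling, marking

The layer masks are computed independently of each other — the second layer
never sees the first layer's output, so an error in one cannot propagate
into the other — and fused pixelwise. The default is intersection
("and"): the wording of the underlying rule is genuinely ambiguous between
"either layer rejects" and "both layers reject", and intersection is the
reading under which the layers filter each other's false positives; the
union variant is exposed as `fusion.mode = or`. Small-area filling deletes
regions strictly below the mean region size, measured by boundary-point
count by default (contour pixels, 8-connected adjacency to background or
image border) with the pixel-count variant as an option; it runs once, not
to a fixed point. With zero or one region the mask is returned unchanged.
The inherited failure mode — a fruit fragmented by occluding foliage into
sub-mean pieces that are then all deleted — is accepted behaviour and shows
up in evaluation, not as an exception.

Evaluation reports pixel precision/recall/IoU and fruit-level
precision/recall under greedy one-to-one matching of predicted to truth
components by descending IoU at a configurable threshold (default 0.5);
empty-vs-empty scores 1.0 by convention.

## Synthetic scenes

The generator emulates the structure of greenhouse imagery: red
quasi-circular fruit (rotated ellipses with radial shading for a spherical
look), elongated green foliage strokes, neutral brown/grey background, two
illumination regimes, and Gaussian pixel noise. Defaults — chosen once as a
realistic scaled-down study and used unchanged by tests and the acceptance
script: 192×256 px scenes, 4 fruit of radius 18–30 px, fruit colour
(190, 60, 50) ± 15, foliage (60, 140, 55) ± 15, background
(120, 110, 100) ± 20, shadow gain 0.45, ±15% horizontal illumination
gradient, noise sd 8, occlusion fraction 0.15. The fruit colour model keeps
`icp` far above the threshold in sunny scenes (so layer 1 is exercised
meaningfully) while background noise pushes a substantial pixel fraction
above it (so fusion with layer 2 has real work to do).

Occluding foliage is drawn as radial strokes that cross a fruit's boundary
and stop well inside it (at ~0.42 of the radius), with per-fruit stroke
angles spaced evenly plus jitter. Two deliberate consequences: the boundary
is occluded by roughly the requested fraction, and a fruit is essentially
never bisected — two near-parallel strokes merging at their inner ends
would pinch off a wedge and split the ground-truth component, which would
make fruit-level scoring measure the generator rather than the detector.
Strokes aimed at one fruit never erase pixels of another. The ground-truth
mask marks *visible* (non-occluded) fruit pixels.

What the generator does not emulate: specular highlights, colour gradients
across ripeness stages, leaf texture and venation, perspective scale
variation, sensor artefacts, or fruit-on-fruit occlusion. Passing the
end-to-end tests therefore demonstrates that the pipeline's machinery is
correct and well-calibrated on scenes with the stated colour/texture
structure — not field performance on real imagery, which depends on
conditions the generator deliberately simplifies.

Training tables label a block target when at least half of its pixels are
truth-fruit (configurable majority fraction). Classifier training is capped
at 600 blocks by a seeded class-balanced subsample: the full 5-scene table
(~3200 blocks, ~12% target) is dominated by background, and an N×N kernel
design matrix makes cost quadratic in N while the decision surface needs
only a fraction of the background examples.

## Problem sizes and determinism

The shipped study trains on 5 scenes (3 sunny, 2 shadow) and evaluates on
20 held-out scenes (10 sunny, 10 shadow); with 192×256 scenes this is
638 blocks per image and a 600-sample training set, which keeps the entire
test suite and the acceptance study in the tens of seconds on one CPU.
Every stochastic stage draws from `numpy.random.default_rng` seeded by a
fan-out of one global seed (fixed per-stage offsets, so stages are
reproducible in isolation); the EM, fixed-point and Laplace iterations are
deterministic, and model files serialize with full float repr — identical
seeds reproduce masks, region tables and model checksums byte for byte.
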