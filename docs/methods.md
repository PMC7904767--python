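# Methods

## The scoring model

Each capsule-endoscopy frame receives a 5-step cleansing score based on the
proportion of mucosa visible behind bubbles, bile and debris. The
endpoints of the scale are fixed by its clinical definition: score 5 means
more than 90% of the mucosa is visible and score 1 means less than 25%.
The interior bins are not pinned down numerically by the scale's published
description, so this package declares equal-width quartile bins below the
0.90 threshold:

| score | visible fraction |
|-------|------------------|
| 5     | ≥ 0.90           |
| 4     | [0.75, 0.90)     |
| 3     | [0.50, 0.75)     |
| 2     | [0.25, 0.50)     |
| 1     | [0, 0.25)        |

This is a declared convention, consistent with both stated endpoints, and
every boundary is half-open so the mapping is a total, monotone step
function (tested exhaustively on a 0.001 grid).

A classifier emits softmax probabilities `p_1..p_5` for the five scores and
the frame's *cleansing score* is the expected value `Σ i·p_i`, a real
number in [1, 5]. The expectation is deliberate: adjacent scores are
genuinely ambiguous even for trained readers, and the expected value turns
that calibrated uncertainty into a graded quantity instead of forcing a
hard argmax. It is linear in `p`, bounded by [1, 5], and monotone under
first-order stochastic dominance (property-tested).

Case and segment averages are arithmetic means of frame scores. The case
average pools all frames rather than averaging the three segment means;
with the tertile sizes differing by at most one frame the two definitions
almost coincide, but pooling matches the "sum of scores over number of
frames" definition exactly. Values are kept at full precision internally
and displayed to one decimal.

## Clinical grading scale

The quantitative grading scale works from a per-frame binary judgment: a
frame is *invisible* when more than 50% of its mucosa is obscured, i.e.
`visible_fraction < 0.5`, with exactly 50% counting as visible (strict
inequality). The time-ordered frame sequence is split into three
contiguous tertiles of equal frame count (earlier tertiles take the
remainder when `n mod 3 ≠ 0`); splitting is by frame count, not by time
span. Each tertile's invisible-frame fraction maps to a segmental grade:

| grade | invisible-frame fraction |
|-------|--------------------------|
| 1     | < 0.05                   |
| 2     | [0.05, 0.15)             |
| 3     | [0.15, 0.25)             |
| 4     | ≥ 0.25                   |

The printed form of the scale ("5–15%", "15–25%", "> 25%") is ambiguous at
exactly 5/15/25%; we resolve all three boundaries left-closed/right-open
with grade 4 at ≥ 25%, a single consistent strictness direction, and test
all bins exhaustively. The three segmental grades sum to the overall
grade — A for 3–5, B for 6–8, C for 9–12 — and preparation is clinically
adequate iff the overall grade is A or B. The original scale's separate
fluid-transparency sub-score is intentionally not implemented: opaque
fluid counts as invisible mucosa, transparent fluid as visible.

## Synthetic data generator

Real capsule videos are not redistributable, so validation runs on
synthetic frames with exact ground truth. A frame is a 64 px square RGB
image (configurable; 64 px keeps a three-pool CNN workable at desk scale)
of reddish-pink mucosa — smoothed-noise shading with darker fold lines so a
classifier has learnable structure — partially covered by one obscuration
category:

* **bubble** — bright circular clusters (union of random discs),
* **bile** — a yellow-green translucent wash pooled at large spatial scale,
* **debris** — dark irregular mid-scale blobs,
* **clean** — at most fine pale specks (requires ≥ 0.90 visible).

The obscured region is the upper level set of a category-shaped random
field, thresholded at exactly the pixel count nearest
`(1 − visible_fraction)·n_pixels`. The achieved visible fraction therefore
matches the request to within half a pixel (±0.00012 at 64 px, far inside
the ±0.02 contract), `mask.mean()` equals the stored ground truth exactly,
and the frame's true score follows by the bin table above. All randomness
descends from a single seed through numpy's splittable `SeedSequence`, so
frames and cases are bit-reproducible.

Cases draw per-frame visible fractions from two uniform ranges —
[0.55, 1.0] for visible frames, [0.05, 0.45] for invisible ones, kept away
from the 0.5 boundary so pixel quantisation can never flip a frame's
invisibility — with the number of invisible frames per tertile being the
count nearest the requested rate. Cohorts mix adequate cases (per-tertile
invisibility rates below 0.12, giving grades 1–2) with inadequate ones
(rates 0.30–0.60, giving grade-4 tertiles); the default inadequate
fraction is 8/96, the proportion observed in the clinical validation
cohort this package models.

What the generator does *not* emulate: real endoscopic optics (vignetting,
specular highlights, motion blur), lesions, gradual transitions between
bowel segments, or correlated cleanliness along the video. Passing tests
therefore demonstrate the pipeline's arithmetic and the training
protocol's behaviour, not clinical performance on patient videos.

## Classifiers

The classifier contract is one method: frame in, five probabilities
summing to 1 out. Two implementations ship:

* **Oracle classifier** — reads the synthetic ground truth; with smoothing
  `s` it places `1 − s` on the true score and splits `s` over the adjacent
  scores (all of it to the single neighbour at scores 1 and 5). With
  `s = 0` the expected-value score equals the true score exactly, which
  gives the scoring and grading stages an exact end-to-end oracle.
* **Reference CNN** — a small numpy network: three 3×3 conv + ReLU + 2×2
  maxpool blocks (8/16/32 channels), a multi-scale descriptor formed by
  concatenating each block's global-average-pooled activations, frozen
  standardisation of that descriptor against training-set statistics, and
  a linear softmax head. The multi-scale readout matters: shallow blocks
  carry the colour statistics that distinguish bright foam, yellow-green
  bile and dark debris from pink mucosa, while deeper blocks add texture.
  Training is plain SGD on cross-entropy with hand-written backprop.

Training follows the two-phase fine-tuning protocol: phase 1 trains the
head alone (conv stack frozen — features are precomputed once, so the
phase is cheap) and phase 2 trains all layers at a lower learning rate.
The desk-scale defaults are 200 head steps at learning rate 0.01 and 400
full-network steps at 0.0001, both with batch size 24 — the batch size and
learning rates of the clinical protocol with step counts scaled to minutes
of CPU. The loss is cross-entropy (the protocol's loss is not specified;
cross-entropy over the five classes is the standard choice), input
resolution 64 px, no augmentation. Determinism is a documented contract:
fixed seed plus single-threaded execution reproduces training
bit-for-bit; the seed tree (init, per-phase batch sampling) descends from
one root seed.

At these defaults with 200 frames per class, held-out Top-1/Top-2 accuracy
is well above the 20%/40% chance levels (the acceptance run at 500 frames
per class is recomputed by `scripts/acceptance.py`). Top-k ties are broken
toward the lower class index via a stable sort — documented because a
uniform prediction then always nominates classes {1, 2}.

## ROC analysis and cut-off

Case average scores are compared against clinical adequacy with the rule
*score ≥ threshold → predicted adequate*. The sweep visits +∞, every
distinct observed score in descending order, and −∞; tied scores move
together, so the trapezoidal AUC equals the tie-corrected Mann–Whitney
`U/(n₊·n₋)` (asserted against scipy and scikit-learn on random instances).
Cut-off selection supports Youden's J (default; the selection rule used
for published cut-offs is not stated, and Youden is standard practice) and
minimum distance to the (0, 1) corner, with ties resolved toward the
higher threshold. The reported threshold is the midpoint between the
optimal distinct score and the next lower one — the convention that
produces quarter-point cut-offs such as 3.25 — falling back to the
attained score itself when no lower score exists. Group summaries report
mean, sample SD (n−1 denominator, absent for single-member groups), min
and max; inferential statistics (ANOVA, post-hoc tests, AUC confidence
intervals) are out of scope.

`simulate_score_cohort` draws case-score cohorts directly at the modelled
clinical statistics — 88 adequate cases at mean 4.0, 8 inadequate at 2.9,
both SD 0.4, clipped to the attainable [1, 5] — for Monte-Carlo studies of
cut-off recovery. Note that with only 8 negatives the empirical AUC and
Youden cut-off have substantial sampling spread (AUC sampling SD ≈ 0.02
around a true value of Φ(1.1/(0.4√2)) ≈ 0.974): roughly 15% of replicates
fall below AUC 0.95, and the recovered cut-off's 90% range is about
[3.1, 3.65]. This spread is a property of the cohort statistics, not of
the estimator.

## Numerical and degenerate-input conventions

* Probability vectors must be nonnegative and sum to 1 within 1e−6;
  anything else is rejected, not renormalised.
* Tertile splitting requires ≥ 3 frames and strictly increasing
  timestamps; the generator enforces strict increase even under jitter.
* ROC analysis requires both classes present; empty segments, empty
  groups and empty score lists raise named errors rather than NaN.
* Grading rejects missing visibility annotations naming the offending
  frame.
* Checkpoints are numpy `.npz` archives with a format tag
  (`capclean-cnn-v1`); unknown tags are rejected on load.
* Reports are JSON with `schema_version: "1"`, validated by the pydantic
  models in `capclean.pipeline`.

## Problem sizes

Default test and acceptance runs use 64 px frames; cohorts of 96 cases ×
30 frames (ground-truth-only generation where pixels are not needed);
1,000-case oracle round trips; 200-replicate Monte-Carlo cut-off studies;
and training runs of 200–500 frames per class with the 200 + 400 step
schedule. These sizes were chosen so the full validation completes in
minutes on one CPU while keeping every statistical check comfortably
powered.

## Known limitations

* Synthetic frames are stylised; no claim is made about accuracy on
  patient videos, and the published clinical accuracies are not
  reproduction targets.
* The interior score bins and the grading-scale boundary conventions are
  declared here, not fixed by the published scale descriptions.
* The reference CNN is a deliberately small from-scratch network, not a
  pretrained deep architecture; it demonstrates the training protocol and
  the classifier contract, not state-of-the-art frame classification.
* Frames are assumed pre-trimmed to the small bowel and pre-extracted
  from the proprietary video container; lesion detection is external to
  this package (lesion labels can be joined onto the manifest for group
  summaries).
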