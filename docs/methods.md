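# Methods

This note records the models, the synthetic-data design, parameter
defaults, and the numerical and design choices made where the design
was genuinely open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Pipeline model

Each lesion line (mel, bcc, asl, sk, vv) has an independent three-level
binary detector; the slide-level hierarchy composes them.

**Patch level.** Slides are rescaled (bilinear) to the line's base MPP
and tiled into square, half-open, row-major windows; a trailing partial
row/column is padded with white and flagged rather than dropped, so
probability maps align with the slide extent (padded tiles are then
mostly removed by the tissue filter, which measures tissue fraction
over the full padded window; threshold 0.1). Patches are labeled
positive when their pixel overlap with any annotation mask of the
line's label vocabulary is at least `min_overlap_fraction` (default
0.5 of the patch area — a balanced choice; the boundary behavior is
unit-tested). Training minimizes binary cross-entropy with Adam and
cosine annealing; each epoch ends with a validation pass (pixel
normalization only — no augmentation, no updates) and the parameters
with the best validation AUC are kept, ties broken by the lower
class-balanced validation cross-entropy (both classes weighted
equally: the plain loss is dominated by the abundant negative patches
and anti-selects confidence on the rare positives, which the fixed 0.8
positivity bound requires). The tie-break matters at desk scale, where
AUC saturates early while confidence is still growing; when a split
leaves a single-class validation set the checkpoint falls back to
validation (then training) loss. Warm-started fits (the ROI stage and
all semi-supervised fine-tuning) use a reduced learning rate
(`warm_lr`, default 2·10⁻³ vs 8·10⁻³) — full-rate Adam steps collapse
an already-converged small ReLU net — and seed the checkpoint search
with the initial weights, so fine-tuning can only keep or improve the
validation metric, never regress it (the release rule the regression
contract encodes). Inference uses test-time augmentation over the closed 8-element
dihedral group; the 8 probabilities are sorted before averaging so the
TTA output is exactly (bitwise) invariant under dihedral transforms of
the input. A patch is called positive iff its TTA probability is
strictly greater than 0.8. Production defaults follow the published
configuration: 250 epochs, batch 64, 20% WSI-level validation split,
patch 128 px at 0.547619 MPP (mel/bcc/asl) or 256 px at 2.1905 MPP
(sk/vv). The printed source of the two base-MPP values runs the two
columns together ("0.5476192.1905"); this package reads them as
0.547619 and 2.1905.

**ROI level.** The binary map is cleaned by removing 8-connected
positive components smaller than `min_component_patches` (default 3
cells; the cleanup rule is otherwise unspecified upstream). Remaining
components are ranked by positive-cell count descending, ties broken
by the component's top-left cell (row, then column). Area and
"density" orderings coincide for solid components on a binary map; a
density ordering (cells per bounding-box cell) is available via
`roi_order="density"`. The top N components (default N = 10, a free
hyperparameter) each yield one ROI window (1024 px for mel/bcc/asl,
512 px for sk/vv; desk scale 48 px) centered at the component centroid
in pixel coordinates and clipped — not padded — to the slide, so
embeddings see only real pixels. A slide with no surviving components
contributes exactly one uniformly random tissue-located ROI,
guaranteeing a nonempty MIL bag; the fallback draws from a per-slide
deterministic RNG (derived from the slide name) so a slide's bag is
identical across training, release gating, and evaluation. Every ROI inherits
the slide's binary line label. The ROI classifier shares the patch
architecture and is initialized from the patch checkpoint (body and
head; the GAP body makes the input-size change legal) and fine-tuned
at a lower learning rate — warm starts tolerate far less step size
than fresh training before the ReLU features collapse.

**Slide level.** One bag of post-GAP, pre-head ROI embeddings per
slide is pooled with gated attention (hidden width 64; attention
weights are nonnegative and sum to 1) and a linear+sigmoid head gives
the slide probability; the call uses probability ≥ 0.5 (the ≥
convention at the boundary is this package's choice). Training is one
bag per step with the same loss/optimizer/schedule and checkpoint
rule. The small attention net is bistable on some data draws, so
`fit` runs a few random restarts (default 3) and keeps the best
validation metric; a warm start uses a single run.

**Hierarchy.** QC first: per-section labels from the hybrid classifier,
slide flagged iff strictly more than 25% of sections are bad; flagged
slides are routed to manual review with no lesion analysis. Then the
melanocytic module; a positive call stops the cascade. Then BCC and
ASL both run; a joint positive resolves to the higher slide
probability with ties to BCC (configurable) — no tie rule is specified
upstream. Then, only for non-excision specimens, SK and VV; both may
be positive and both are reported, the higher probability becoming the
final line. Melanocytic subtyping runs before margin status.

**Subtyping.** Severity ladders, most severe first: mel
severely_atypical > mildly_atypical > benign_nevi (the fine-grained
nevus vocabulary collapses into these tiers); asl scc_invasive >
sccis > ak; bcc infiltrative > nodular > superficial. ROIs are
expanded to the bounding box of their lesion component plus one patch
of context per side. One binary classifier per rung (that subtype vs
the line's other subtypes), trained only on line-positive slides with
the standard loop. Inference walks the ladder most-severe-first and
assigns the first rung whose classifier scores any expanded ROI
strictly above 0.5 ("any ROI over threshold" is this package's
aggregation; per-ROI vs pooled is unspecified upstream); no rung
firing means `inconclusive`. For mel/ASL lower rungs are never
consulted after a hit (call-count instrumented); BCC evaluates the
remaining rungs and reports `mixed` when at least two fire, the most
severe firing rung remaining the margin-relevant primary. Conflicting
supervised subtype masks on one ROI resolve to the most severe, with a
log entry.

**Margin.** Ink pixels are detected in HSV (hue in degrees ∈ [90, 165],
saturation ≥ 0.25, value ≥ 0.15); a patch is a margin patch when at
least 5% of its pixels are ink. These thresholds are this package's
defaults (config-exposed); only the colorspace is fixed upstream.
Margin status applies to all melanocytic and BCC subtypes and to ASL
invasive SCC and SCCIS — never AK, SK, or VV. Status is positive iff
the lesion and margin maps share at least one grid cell (a single cell
suffices; no minimum overlap count, no distance measurement).

**Semi-supervised loop.** Per line and weak slide the truth table is:
prediction+/diagnosis+ → TP/positive; −/− → TN/negative; +/− →
FP/negative; −/+ → FN/excluded and flagged for manual ROI review
(flagged slides are emitted to a queue and otherwise ignored; their
re-entry path is unspecified upstream). Auto-generated masks are the
line's binary probability map with components dropped when smaller
than 3 cells or when their mean raw probability is below 0.9 (the
"low-confidence/noisy" cleanup is this package's quantification),
rescaled to the supervised annotation scale and written one mask file
plus manifest row per component. Negative pseudo-labels carry a single
empty-mask sentinel row so the slide enters patch training as
all-negative. Reviewer disagreement drops the slide; a missing verdict
is treated as pending and dropped with a warning. Merging keeps the
supervised split untouched and splits weak slides by case_id order,
the last 20% to validation (the ordered split ratio mirrors the
supervised one; only the order-based rule is fixed upstream). All
three levels are then retrained per line from the prior checkpoints at
the reduced warm-start rate, and each fine-tuned line stack passes a
release gate: it is released only if its end-to-end slide-level AUC on
the merged validation slides is equivalent or superior to the prior
stack's, otherwise the prior stack stays in place — the regression
test a new version must pass before release.

**QC.** Per-section features: variance of the 3×3 discrete Laplacian
on Rec.601 grayscale (blur); scan coverage = fraction of the section
bounding box with grayscale below 243 (incomplete scans); mean and
standard deviation of grayscale intensity (0–255); brightness = mean
per-pixel max channel / 255; luminosity = mean Rec.601 luma / 255
(both formulas are this package's definitions — the feature names are
fixed upstream, their formulas are not); mean HSV saturation. The
section classifier is a hybrid: a random forest on the feature vector
and a small CNN on the resized section image, fused by the unweighted
mean of their per-class probabilities (the fusion rule is this
package's choice); exact ties resolve by severity priority
incomplete > blurry > folding > artifact > ok. Each section gets one
label.

## Statistics

Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) per line, each
with a 95% normal-approximation interval p ± 1.96·√(p(1−p)/n) on the
relevant denominator, clipped to [0, 1]; a zero denominator leaves the
metric undefined and flagged. ROC curves sweep thresholds over the
unique scores; AUC is the trapezoid area, which equals the
Mann–Whitney statistic P(s⁺>s⁻) + ½P(s⁺=s⁻) under rank-averaged ties
(tested against a pairwise oracle and scikit-learn).

## Synthetic slides

The generator emulates multi-section H&E-like slides: elliptical
tissue sections in a pale-pink palette on a near-white background;
each lesion class renders a distinct base hue plus a
spatial-frequency band of Gaussian-filtered noise, chosen so tiny CNNs
learn them in minutes; subtype rungs shift the color mildly within the
line's hue family and change the noise band more strongly. Lesion
blobs are disks clipped to their section (default radius 0.3·section
size, spanning ~10 grid cells at desk scale so a lesion, like its
clinical counterpart, covers many patches), placed with enough jitter
(±size/8) that some lesions reach the section edge — margin-positive
specimens exist in every cohort. The green marking dye is a band along
each section's lower (non-epidermal) edge (width size/8), alpha-blended
(α = 0.5) over the tissue so inked lesion edges keep their texture
through the tint, as surface dye does; the blend's hue (~107–137°)
stays within the detector's green range over both lesion and plain
tissue. QC defects are local
Gaussian blur, a darkened fold strip, a saturated magenta blotch, and
an interior blank stripe (kept interior so the section remains one
component and its bounding-box coverage drops, as an incomplete scan's
does). A `difficulty` knob blends all motifs toward the common tissue
motif, monotonically shrinking inter-class texture distance.
Generation is bitwise deterministic given the seed, and the slide-level
label for a line is positive iff some section carries that line's
lesion.

What the generator does **not** emulate: stain physics and scanner
color profiles, nuclear/cellular morphology, texture variability
within a class, mimicker lesions, pen ink other than the margin dye,
or annotation noise. Passing the end-to-end studies therefore shows
that the *pipeline machinery* — tiling, mapping, selection, pooling,
hierarchy, margin and SSL logic — is correct and trainable, not that
the tiny backbones would reach clinical performance on real H&E.

## Desk-scale study conditions

The synthetic studies use `desk_line_config`: 16 px patches at
1.0 MPP, 48 px ROIs, N = 4, tiny 3-conv backbones (width 8), 30 patch
epochs (lr 8·10⁻³), 8 ROI epochs at the warm-start rate, 30 MIL
epochs, and a 2-cell probability-map speck filter (a desk-scale lesion
spans only ~10 grid cells, so the production 3-cell cleanup is scaled
down with it); slides are 96 px sections, two per slide. The detection
study
trains on 48 slides (8 per line + 8 lesion-free) under one shared
class-stratified WSI split (20% validation), so every line's
validation set contains positives and negatives and per-line
validation AUCs stay finite and comparable across the supervised and
fine-tuned models; it evaluates a balanced 60-slide held-out cohort.
The SSL study adds 18 weak slides;
the QC benchmark uses 200 sections (80/20 split); the margin study 40
controlled-geometry slides; the subtype benchmark 90 native-resolution
lesion-center crops per line (resizing would compress the
spatial-frequency bands that define the severity rungs) with width-16
classifiers on an 80-epoch schedule — the middle rung is a
non-monotonic frequency discrimination and the hardest of the three. These sizes were chosen so the full set of studies completes in
minutes on one CPU while every stage still has enough data to learn
its synthetic task. Augmentation defaults keep the interpolating
geometric operations (crop-resize, affine) off: on 16 px patches they
erase the texture band that defines the classes and hold patch
confidence below the fixed 0.8 positivity bound; flips, rotations,
blur, noise, HSV shift, stain mix, and Mixup (α = 0.2, Beta-sampled)
stay on. All augmentation operations remain available and
configurable for larger patches.

## Numerical choices and degenerate inputs

* All trainable models run on an in-repo numpy reverse-mode autodiff
  core (im2col convolution, gradient-checked against finite
  differences); the `se_cnn` registry entry is a genuine
  squeeze-excitation residual CNN at reduced depth, standing in for the
  full-scale SE-ResNet family whose pretrained weights are out of
  scope.
* BCE is computed on logits in the stable max-form; softmax subtracts
  the row max; sigmoid clips logits at ±60.
* TTA averages after sorting — exact dihedral invariance by
  construction.
* Attention normalization is asserted to 10⁻⁶; permutation invariance
  of bag predictions holds to 10⁻¹².
* Empty tissue masks are legal (no patches, random-ROI fallback);
  empty bags, zero-section QC, and degenerate (<1 px) rescales raise.
* A mask-manifest row with an empty `mask_file` is the negative-slide
  sentinel and contributes no positive pixels.
* The U-Net-style segmenter fits with a few random restarts (kept by
  final training loss; its 5-epoch convergence is init-sensitive) and
  calibrates its decision threshold on the training pairs, where the
  raw sigmoid is biased at the 1-px boundary halo.
* The deterministic baseline segmenter (HSV saturation ≥ 0.08,
  closing radius 2, small-object removal < 64 px) is exactly optimal
  on the synthetic renderer, whose tissue boundary is a crisp color
  edge; the tiny trainable encoder-decoder approaches but cannot match
  it (a 1-px boundary halo remains), so it is tested against a high
  absolute Jaccard bar with the baseline as the upper bound rather
  than for strict superiority.

## Known limitations

* Synthetic realism is intentionally minimal (see above); none of the
  measured numbers transfer to clinical slides.
* The vendor slide format is a plain tiled TIFF with an MPP record;
  proprietary scanner formats are out of scope (a multi-page file's
  first page is treated as level 0).
* SCC grading/differentiation and Merkel-cell screening are not
  implemented.
* The reviewer-agreement step models dermatopathologist review as an
  input table; no reviewer behavior is simulated.
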