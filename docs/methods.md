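# Methods

This note documents the models and procedures implemented in
`nodulecl`, the assumptions behind them, the parameters that matter, and
the design choices made where the design was genuinely open.

## Difficulty model

**Handcrafted score.** Per-slice difficulty is the sum of four factors
computed from annotations and image quality: nodule count (0.5 / 1.0 /
2.5 / 4.0 for 0 / 1 / 2–3 / ≥4), smallest-nodule area (0.5 with no
nodule; 1.0 above 1000 px²; 2.0 in 400–1000 px²; 3.0 below 400 px²),
shape irregularity (0.5 / 1.0 / 2.0 for zero / one / several irregular
nodules), and image quality (0.5 / 1.0 / 2.0 for high / medium / low).
The sum is therefore always in [2.0, 11.0]. Choices left open by the
factor definitions, resolved here:

- *Irregularity* is a box aspect ratio strictly above 2.0 — a 2:1 box is
  a conventional elongation cutoff; configurable.
- The "regular" shape category is operationalized as "no irregular
  nodule", keeping the three-way rule total and deterministic.
- Area thresholds are interpreted at the stored 512×512 slice
  resolution; pixel thresholds are only meaningful at a fixed scale.
  Band edges (exactly 400 or 1000 px²) belong to the middle band.
- Areas are mask foreground counts when a segmentation mask exists,
  otherwise box areas.

**Model-driven score.** A teacher detector is trained on part of the
training pool and applied to slices it never saw; each scored slice gets

    c_det = clip(λ₁(1−p̄) + λ₂|N_pred−N_gt|/max(N_gt,1)
                 + λ₃ min(0.5 N_pred, 2.0), 0.5, 8.0)

with λ₁ = λ₂ = 3.0 (confidence and count mismatch reflect detector
failure most directly) and λ₃ = 1.0 (density is an auxiliary penalty).
`p̄` is the mean post-NMS confidence, or, when nothing survives NMS, one
minus the mean of the top-5 pre-NMS candidate scores — a slice where the
detector had strong candidates that died in post-processing is still
hard. Fewer than five candidates are zero-padded before averaging,
which biases `p̄` upward (slice looks easy) only when the detector truly
found almost nothing — conservative and total. Slices with no
prediction record at all are scored with `p̄ = 0` (worst case): missing
output is evidence of difficulty. No confidence floor is applied to
post-NMS boxes; all supplied boxes enter `p̄`.

In-sample scoring is rejected outright: `score_heldout` refuses any
slice whose patient is outside the held-out scoring set and names the
offending patients, because difficulty measured on training slices
reflects memorization, not difficulty.

**Fusion and tiers.** `c_hybrid = a·c_manual + (1−a)·c_det`, `a = 0.2`
by default (the ablation optimum; `a = 1` is purely handcrafted, `a = 0`
purely detector-driven). Tier cut-points are ≤ 3 (simple), (3, 6]
(medium), > 6 (complex); both boundaries are inclusive on the lower
tier. Because the combination is convex, the fused score always lies
between its two sources.

## Curriculum construction

Stages are cumulative: stage 1 uses simple positives with high-quality
negatives; stage 2 adds medium positives and medium-quality negatives;
stage 3 is the full training set. Two ambiguities resolved here:

- Negative (nodule-free) slices *do* receive a handcrafted score (their
  count and size factors are both 0.5 by the no-nodule rules), but their
  stage membership is governed by image-quality tier — the only quality
  notion the staging rules quantify for negatives.
- Whether a stage continues from the previous stage's weights or
  re-initializes is left to the external trainer; the emitted stage
  config carries an `init_from_previous` flag (default true) so both
  options are representable.

Stage configs carry the published schedule as defaults — resolutions
512/640/768, epochs 50/100/100, learning rates 3e-3/2e-3/1e-3, loss
weight triples (box, cls, dfl) = (2, 4, 0.1) / (5, 2, 0.5) /
(7, 1.5, 1.0), augmentation (rotation°, translation, scale) =
(3°, 5%, 10%) / (8°, 10%, 20%) / (12°, 15%, 30%) — as does the
no-curriculum baseline config (640 px, batch 32, ≤500 epochs, SGD lr
1e-4, momentum 0.937, weight decay 5e-4, patience 30, loss
(5, 2, 0.3)). The toolkit emits these values; it does not train.

## Preprocessing protocols

**Quality metrics.** Sharpness is the variance of the 3×3 discrete
Laplacian over the lung region; contrast (and the intensity-
heterogeneity field, which coincides with it under this choice) is the
intensity standard deviation over the lung region, on 8-bit values. A
slice is high quality iff Laplacian variance > 500 **and** contrast
> 30; low iff Laplacian variance ≤ 150 **or** contrast ≤ 15 (the high
thresholds scaled down ~3×, configurable; only the high boundary is
externally fixed); medium otherwise. No separate "structural
conspicuity" metric is computed — no operational definition exists for
it, so the quality tier rests on the two thresholded metrics. Without a
lung mask the whole image is treated as lung.

**HU handling.** HU-valued inputs are windowed to [−1000, 400] (the
standard lung window) and mapped linearly to 8-bit before CLAHE and
metric computation; 8-bit inputs pass through.

**CLAHE.** Contrast-limited adaptive histogram equalization via
scikit-image's `equalize_adapthist` on an 8×8 tile grid with clip limit
0.02 in its normalized convention (the fraction of a tile's histogram).
Constant images are returned unchanged.

**Pad-resize.** Uniform scale `s = target / max(H, W)`, bilinear for
images, nearest for masks, symmetric zero padding; boxes ride the same
affine map, which is exactly invertible on the content region (round
trips are within 0.5 px). Pixel spacing is divided by `s` and nodule
areas multiplied by `s²`.

**Filtering and sampling.** Nodules under 3 mm in diameter are dropped
(strict `<`; diameter is the larger axis-aligned box extent times the
pixel spacing — a conservative, mask-free definition, since no other is
fixed); slices are never dropped by this filter, so it is idempotent.
Slice sampling keeps every nodule-bearing slice and retains non-nodule
slices at a 2-per-positive ratio, best-quality-first (quality tier, then
sharpness, then contrast, with a seeded tie-break) — matching the stated
preference for high-quality negatives while staying deterministic. If
too few negatives exist, all are kept and a warning is logged.

**Splits and subsets.** All splitting is patient-atomic and
seed-deterministic: patients are shuffled, then greedily assigned to the
subset with the largest remaining slice deficit, which tracks the target
slice fractions (80/10/10; realized fractions within ±3 points on
realistic cohorts). The teacher split holds out 20% of patients purely
for difficulty scoring and divides the remaining 80% into 90/10
teacher-train/val — 72/8/20 overall. Proportional subsets (e.g. 1/2,
1/5, 1/10) add shuffled patients while this brings the slice count
closer to the target (±5%); fixed-budget subsets (seed 42 by default)
append patients in seeded order and stop at the first patient that
reaches the budget, included whole.

## Evaluation

Matching is confidence-greedy with one-to-one ground-truth assignment:
predictions are visited in descending confidence and claim the unmatched
ground-truth box of highest IoU, provided IoU ≥ τ; unmatched ground
truths are false negatives. This is the standard convention behind the
mAP family, which the metric definitions themselves leave open. AP is
the exact area under the monotone precision envelope over every recall
change-point (no 11- or 101-point sampling), pooled over all slices
(micro averaging); mAP50–95 averages AP over τ ∈ {0.50, 0.55, …, 0.95}.
The precision/recall operating point applies a 0.1 confidence threshold
at IoU 0.5, while AP ranks the full prediction list; both conventions
are recorded in the result metadata. With no ground truth anywhere, AP
is undefined and reported as 0. Boxes use 0-based, half-open pixel
intervals throughout, so areas and IoU are exact integer-free
arithmetic.

## Synthetic fixtures

The generator emulates the *statistical* structure the toolkit consumes,
not anatomy: per-slice nodule counts (default distribution 0.35 / 0.30 /
0.15 / 0.10 / 0.06 / 0.04 over 0–5 nodules, so most slices have at most
one nodule), rasterized elliptical nodules with controllable pixel area
(default 150–2500 px²) and axis ratio (1–3), a darker circular lung
region in a smoothed random field, white-noise detail whose amplitude
sets the lung-region contrast (default 12–70, straddling the 30
threshold) and whose Gaussian blur (default σ 0–3 px) drives the
Laplacian-variance sharpness measure across the 500 threshold, pixel
spacing 0.7 mm/px (typical in-plane chest-CT spacing, so the 3 mm filter
bites at ~4-px boxes), and patient grouping. Recorded nodule areas are
the exact mask foreground counts; nodules are placed without overlap,
resampling size and position as needed.

The simulated teacher detects each ground-truth box with probability
equal to its quality knob `q ∈ [0, 1]`, jitters surviving boxes in
proportion to `1 − q`, draws confidences from a Beta distribution with
mean `q` (concentration 12), adds spurious boxes at Poisson rate
`0.4(1 − q)`, and always emits at least five pre-NMS candidate scores
(background candidates with Beta mean `0.3(1 − q)`, exactly zero for a
perfect teacher). At `q = 1` its output is exactly the ground truth at
confidence 1.0. Integration tests score the fixtures against a weak
teacher (`q ≈ 0.3–0.4`), emulating the early-training regime in which
model-driven difficulty is informative; under these default conditions
the fused score populates all three tiers.

What the fixtures do *not* emulate: HU calibration, anatomy
(vessels, airways, pleural contact — the main source of real false
positives), inter-scanner protocol variation, 3D slice continuity, and
annotation noise. Tests passing on fixtures therefore validate the
*mechanics* of scoring, scheduling, splitting and evaluation — not
detection performance on real CT, which depends on an external trainer
and real data.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.default_rng` seeds;
  identical seeds give byte-identical artifacts across runs.
- Constant images: contrast 0, Laplacian variance 0, quality tier low;
  CLAHE returns them unchanged.
- Precision and recall are defined as 0 on an empty denominator.
- Tie-breaks: greedy split assignment prefers the earlier subset on
  equal deficits; prediction sorting is stable (insertion order breaks
  confidence ties).
- YOLO label I/O writes 10 significant digits, so write–read round
  trips are exact to ≪ 0.5 px; labels are clipped to image bounds on
  read.
- Problem sizes in the test suite and the acceptance script (hundreds
  to ~1100 slices at 128–512 px) were chosen as the smallest scales at
  which every protocol's contract is observable.

## Known limitations

- The toolkit emits curricula and configs but does not train detectors;
  claims about end-task mAP gains are outside its scope.
- The quality model reduces "image quality" to two scalar metrics; real
  slice-quality assessment may need more (noise spectra, artifacts).
- The sub-3 mm filter and size factors assume isotropic in-plane
  spacing.
- Micro-averaged AP is the only averaging mode; per-patient averaging
  is not implemented.
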