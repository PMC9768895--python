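# Methods

## Pipeline model

The package segments the amyloid-positive area of reference-normalized PET
volumes, one 2D network per (zone, plane) pair. The processing chain is:

phantom simulation → pons-ratio normalization → threshold ground truth →
slice extraction → U-Net training with the soft-IoU loss → binarization,
dilation and hemispheric-swap thresholding → confusion-matrix evaluation.

Each stage is an independent module with a functional surface; the training
stage is additionally wrapped as a scikit-learn estimator (`UNetSegmenter`)
so it composes with sklearn model selection and cloning.

## Synthetic phantoms

`phantom.generate_phantom` renders a parametric scene: a brain-shaped
ellipsoid at background uptake 1.0 (arbitrary units), five disjoint target
zones — bilateral ellipsoid pairs for frontal, lateral temporal, parietal
and striatal zones, a midline ellipsoid for the posterior cingulate +
precuneus — a midline pons ellipsoid low in the volume, and a separate
cerebellar-surrogate background region used as the thresholding reference.
Positive zones carry `uptake_ratio` × background (default 2.0, roughly the
contrast of a clearly positive flutemetamol read after pons normalization);
the pons itself sits at background level (no specific binding). The scene is
blurred with a Gaussian point-spread function of 3.0 mm FWHM at 2.0 mm
isotropic voxels — the post-reconstruction filter width typical of clinical
amyloid protocols — and corrupted with additive white Gaussian noise
(default σ = 0.05, i.e. 5 % of background), clipped at zero to keep uptake
nonnegative. Additive Gaussian is the weakest noise assumption; it is *not*
a scanner model.

What the phantoms deliberately do not emulate: anatomy (gyri, white/gray
contrast), attenuation/scatter artifacts, inter-subject geometric
variability beyond an uptake-ratio jitter, partial-volume effects beyond the
PSF, or color-scale quantization of clinical displays. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that the
network can recover known lesions under controlled contrast and noise — not
clinical-grade performance.

Default desk-scale matrix is 64×64×40; the clinical-scale 256×256×(200→159)
geometry is supported but not used in tests, which would gain nothing from
the extra resolution.

## Normalization and ground truth

The pons statistic is the arithmetic mean over the pons mask (the SUVR
convention; the choice of statistic is otherwise free). Normalization is
exact division, hence idempotent and scale-invariant.

Ground truth is `zone ∧ (voxel > 1.5 × background mean)` with a **strict**
inequality; ties at exactly the threshold are excluded (covered by a
dedicated tie test). The 1.5 factor labels training targets; the separate
1.3 hemispheric-swap factor filters *predictions* — the two are independent
configuration values and are never reconciled. On noiseless phantoms with
ratio-2.0 zones the rule recovers the generating masks exactly, which is the
package's strongest internal consistency check.

## Network and optimization

The U-Net is implemented from scratch in NumPy with analytic
backpropagation (verified against central finite differences to ~1e-10 on
every layer type). Choices:

- Same-padded 3×3 convolutions (predictions overlay the input slice
  directly), He-initialized, element-wise ReLU.
- 2×2 max pooling; gradient routed to the argmax (first index on ties).
- Learned upsampling by 2×2 stride-2 transposed convolution.
- Final 1×1 convolution to 2 classes; per-pixel softmax with max-shift
  stabilization.
- Depth 2 / base 8 by default → 11 conv layers, 29,330 parameters. Channel
  widths double per stage; the width schedule is this package's choice.

The loss is the mean per-slice soft-IoU: the soft (probabilistic)
intersection is used during training, the binarized complement — identical
to the Jaccard metric by construction — at evaluation. Empty-vs-empty maps
define loss 0 / metric 1 with a warning rather than NaN, since all-negative
slices are routine. Cross-entropy for slice-level state classification is
exposed with combination weight λ (default 0, segmentation-only; the demo
classifies slices as positive when the predicted mask is nonempty rather
than training a second head).

Optimization is Adam with the standard bias correction. Clinical-scale
defaults (learning rate 10⁻⁵, batch 4, up to 2000 epochs) are kept as the
estimator defaults; the desk-scale demo uses learning rate 10⁻³ and ≤ 60
epochs with early stopping on validation-IoU plateau (patience 15), the
standard setting for a small from-scratch network on easy contrast. Training
aborts with a diagnostic on non-finite loss. All randomness (init, batch
order, augmentation) derives from `random_state`; fits are bit-reproducible.

## Augmentation and splitting

Augmentation is sampled online per slice per epoch — rotations in [−10°,
+10°], x/y translations in [−0.1, +0.1] of the frame size, shear in [−10°,
+10°] — applied identically to image (linear resampling) and mask
(nearest-neighbour, so masks stay binary), with zero fill outside the frame.
Ranges are hard validation bounds. The 80/20 split is seeded and made at the
phantom level so validation slices come from held-out phantoms;
`|train| = round(0.8 n)` clamped so neither side is empty.

Dataset standardization (mean/std) uses global training-set statistics,
stored on the fitted estimator and reapplied at prediction time.

## Post-processing

Binarization is strict `p > 0.5` (a 0.5/0.5 tie maps to background).
Dilation uses a 3×3 square element in 2D; the 3×3×3 cube applies when run
volumetrically. The hemispheric-swap threshold interprets "mean value of the
hemispheric swap of the predicted mask" as the mean *image intensity* under
the left–right mirrored predicted mask — an interpretation, flagged as such;
mirroring is along x and configurable. Consequences the tests document: the
output is always a subset of the prediction, raising the factor never adds
pixels, and a perfectly symmetric bilateral lesion empties its own mask
(the contralateral reference equals the lesion). For that reason the demo
phantom lateralizes its lesion to one hemisphere, giving the swap a genuine
amyloid-free reference; with symmetric bilateral disease the stage is
counterproductive and should be disabled.

## Evaluation

Confusion counts are exact pixel tallies. Metrics with zero denominators are
NaN ("NA" in reports), never 0, and are excluded from aggregation.
Presentation rounding follows the field's convention: IoU to 3 d.p.,
percentages to 1 d.p. Reports are labelled with their granularity
(pixel-level vs case-level) because the two are routinely conflated in the
literature; this package computes pixel-level values in the demo. The F1
identity 2·P·S/(P+S) is enforced by construction and cross-checked.

## Demo problem sizes

The end-to-end demo trains frontal/axial on ten 64×64×40 phantoms (≈ 100
slices, 8/2 phantom split), depth-2/base-8 network, ≤ 60 epochs — about two
minutes on one CPU — and reaches mean validation IoU ≳ 0.9 before
post-processing. These sizes were chosen as the smallest configuration that
cleanly separates success from failure on the phantom task.

## Known limitations

- The NumPy network is CPU-only and desk-scale; it is not a performance
  implementation.
- Phantom realism is deliberately minimal (see above); reported phantom IoU
  values say nothing quantitative about clinical images.
- The hemispheric-swap stage presumes asymmetric uptake; bilateral symmetric
  positivity defeats it by design.
- One network per (zone, plane) means ten models for full coverage; the demo
  trains one pair.
- Slice selection for a zone's network (all slices intersecting the zone
  mask) is a pragmatic choice; clinical slice-selection protocols may
  differ.
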