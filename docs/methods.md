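# Methods

This note records the scientific and numerical choices behind `tumorseg`:
what each stage assumes, which parameters matter, what the synthetic
phantoms do and do not emulate, and where the design was genuinely open.

## Synthetic phantoms

Each phantom is a 2-D axial-slice caricature built from four parts: a dark
background, a bright thin skull ring, a textured brain disk separated from
the ring by a dark CSF-like rim (3 px), and an optional hyperintense tumor
disk strictly inside the brain. Noise is additive Gaussian or Rician
(magnitude of the noisy complex signal, the standard MR noise model); all
intensities are clipped to [0, 1]. The tumor mask is the exact rasterized
disk — the intensity profile may have a soft rim, but ground truth is hard.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| slice size | 240×240 (generator), 64×64 (pipeline studies) | 240×240 matches typical MR slice rasters; the pipeline's study size of 64×64 keeps a 20-epoch CPU training run in the minutes range while preserving the geometry |
| skull ring | inner radius 0.75–0.82 of the half-width, thickness ≈5% of the slice | ring must sit fully inside the field of view with a background margin; at small slice sizes the thickness scales down accordingly |
| brain tissue | mean 0.45, texture sd 0.04 (smoothed Gaussian field) | mid-gray parenchyma with mild spatial texture |
| tumor | radius 9 px at 64×64 (jittered ×0.7–1.3 per image), intensity 0.85, soft rim 1.5 px | hyperintense lesion clearly separable from tissue, small enough to be non-trivial after two pooling stages |
| noise σ | 0.05 (study), 0.02 ("easy" classification suites) | visible but not dominant; Rician available via config |
| modalities | T1/T2/T1CE/FLAIR as per-image gain tags (0.92–1.08) | modalities modulate contrast only; they are metadata, not channels, because the pipeline treats each slice independently |

What the phantoms do **not** emulate: real anatomy (gyri, ventricles,
midline), co-registered multi-channel modalities, bias fields, partial
volume effects, infiltrative tumor margins, or inter-scanner intensity
variation. Passing the synthetic-recovery suite therefore demonstrates the
pipeline's mechanics — shape-preserving segmentation, correct loss
behavior, end-to-end reproducibility — not clinical performance.

## Preprocessing

The 3×3 median filter and the fixed high-pass mask
(−1, 2, −1 / 0, 0, 0 / 1, −2, 1) both use edge replication at borders;
replication avoids the artificial dark rim that zero padding would create
and that the stripper would then mistake for structure. The mask is applied
exactly as printed, as a correlation (no kernel flip): the mask is an
asymmetric high-pass and no flip convention accompanies it, so the
toolbox-standard correlation is used and documented. Since its coefficients
sum to zero, constants are fixed points; after adding the response to the
image the result is clipped back to the declared intensity range.

Z-score normalization uses each image's own mean and population standard
deviation; a constant image raises a degenerate-input error rather than
dividing by zero. Normalization scope is per-image — the desk-scale
analogue of per-patient normalization when each record is a single slice.

## Skull stripping

No published procedure accompanies the stage name, so the stripper is an
intensity/morphology design: Otsu threshold → opening (disk radius 2) →
largest 8-connected component → closing + hole filling → zero outside the
mask. Two details matter:

* Thresholding and component analysis run on a **3×3-median-smoothed**
  copy of the input. Edge enhancement deliberately amplifies texture; on
  the raw enhanced image Otsu lands inside the tissue mode and the
  foreground fragments. A median (not Gaussian) smoother is used because
  the thin dark rim between brain and skull must survive — Gaussian
  blurring bridges it and the ring merges with the brain.
* The output contract is a single connected, hole-free mask. The guarantee
  comes from construction (largest component + fill), not from assumptions
  about the input.

The stage assumes the brain is the largest bright structure in the slice.
It is a plain function, so an atlas-based extractor can replace it for
real data without touching the rest of the pipeline.

## Segmentation network and focal loss

Architecture: conv(3×3, pad 1) + BN + ReLU three times, with 2×2 max
pooling after the first and second blocks; two stride-2 2×2 transposed
convolutions restore resolution; a 1×1 convolution projects to two classes;
softmax per pixel. Glorot-uniform initialization throughout, seeded.

Two places needed a decision where the recipe is internally inconsistent:

* **Pool stride.** The printed recipe pairs a 2×2 pool with stride 1, yet
  also describes the pooling as downsampling and includes an upsampling
  transpose layer. Downsampling (stride 2) is implemented as the default;
  the stride is configurable.
* **Focal exponent γ.** The published table lists the focal value 10,
  which is retained as the `TrainingConfig` default. γ = 10 suppresses the
  gradient of any pixel already above ~50% confidence by three orders of
  magnitude, which makes optimization sluggish; γ = 2 is the recommended
  stable setting and is what the package's own end-to-end studies use.

The loss is the standard per-pixel focal form
`−(1−p_t)^γ · l_t · ln p_t`, averaged over contributing pixels; pixels
labeled 255 are excluded entirely. Class weights `l_k` default to inverse
class frequency computed on the training split, normalized to mean 1 —
the concrete reading of "weights allocated based on complexity" that is
actually computable. Probabilities are clamped to [1e−7, 1] before the
log. The analytic gradient (both with respect to probabilities and chained
through softmax to logits) is verified against central differences in the
test suite to 1e−4 relative error.

Training follows the published hyperparameters: Adam, learning rate 0.001,
minibatch 30, at most 20 epochs, reshuffling every epoch. Early stopping
uses patience 10 on epoch-end validation loss ("validation loss higher
than its running minimum ten consecutive checks"). Batch normalization
uses batch statistics during training and running statistics (momentum
0.1) at inference, the standard convention. Given identical data, config
and seed, training is bit-reproducible: all randomness flows through
`numpy.random.Generator` instances seeded from the config.

## Postprocessing

Global threshold τ on the tumor probability map, then deletion of
connected tumor components with area below `min_region_px`. Defaults:
τ = 0.5, `min_region_px` = 100 at 240×240 (10 in the 64×64 pipeline
config, scaling with slice area), 8-connectivity. No published values
exist for these; they are config-exposed and recorded in every run
manifest. Removal touches only the tumor class, never adds pixels, and is
idempotent.

## Classification

The transfer recipe — replace the final fully connected layer with a fresh
2-way head behind dropout (0.4), optionally freeze the feature extractor,
fine-tune with Adam — is implemented over a backbone protocol. The bundled
backbone is a small inception-style network (stem conv + two blocks of
parallel 1×1/3×3/5×5 branches, 32 features, global average pooling)
trained from scratch at 32×32 input; it exists so the whole recipe runs in
seconds with no pretrained weights. An externally pretrained feature
extractor (e.g. an inception network converted to the layer protocol) can
be passed directly to `adapt_backbone`; inputs are then bilinearly resized
and gray-replicated to three channels as the backbone requires.
Classification uses plain cross-entropy: class imbalance is a pixel-level
problem for the segmenter, not an image-level one here (tumor fraction is
0.5 by construction).

Frozen layers are excluded from the optimizer at construction, so their
weights are bit-identical before and after training — asserted in tests.

## Evaluation

* **70/10/20 split.** Train and test counts use round-half-up in exact
  integer arithmetic (`(7n+5)//10`, `(2n+5)//10`), validation is the
  remainder. This convention reproduces all three published partitions
  (1425 → 998/142/285, 1675 → 1173/167/335, 2470 → 1729/247/494); naive
  floating-point rounding fails at n = 1425 because 0.7·1425 is
  997.4999… in binary floating point.
* **Metrics.** Accuracy, sensitivity/recall, specificity and precision
  from the 2×2 counts, ×100; dice as the harmonic mean of precision and
  recall, which is algebraically 2TP/(2TP+FP+FN). Zero-denominator
  metrics are reported as NaN with a warning, never silently as 0 or 100.
* **Cross-validation.** Record-wise folds are stratified (per-fold class
  counts within ±1, seeded shuffle); subject-wise folds assign each
  subject wholly to one fold, greedily largest-subject-first onto the
  currently smallest fold, with seeded tie-breaking — fold-size spread is
  bounded by the largest subject.

## Problem sizes used in the bundled studies

The end-to-end study configuration is 200 phantoms at 64×64, noise
σ = 0.05, 70/10/20 split, a 32-filter FCNN trained 20 epochs with γ = 2,
and a 15-epoch classifier; it completes in roughly two minutes on one CPU
core and reaches held-out mean dice ≈ 0.88 and classification accuracy
≈ 97% (seed 1). These sizes are the package's chosen desk-scale study
conditions; the architecture defaults (64 filters, 240×240 contracts)
remain available for larger runs.

## Known limitations

* The numpy layer stack is CPU-only and eager; it is meant for desk-scale
  experiments, not BRATS-scale training.
* The stripper's largest-bright-component assumption fails on slices where
  the brain is not the dominant bright structure (e.g. extreme slices near
  the vertex).
* `googlenet_pretrained` is a protocol slot, not bundled weights; the
  package ships no pretrained models.
* Phantom realism limits are listed above; no claim is made about
  performance on clinical data.
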