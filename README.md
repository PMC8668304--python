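# tumorseg

Automated brain-tumor detection in 2-D MR slices: a five-stage pipeline of
preprocessing, skull stripping, fully convolutional pixel-wise tumor
segmentation trained with focal loss, connected-component postprocessing,
and transfer-style binary tumor/normal classification. A seeded synthetic
brain-phantom generator with pixel-level ground truth makes the whole
pipeline runnable and testable on a laptop CPU, with no external imaging
data.

## Who this is for

Researchers and students who want a compact, fully reproducible reference
implementation of the classical FCNN tumor-segmentation recipe — the kind
of pipeline usually demonstrated on the BRATS glioma datasets — that can be
exercised end to end in minutes. Every stage is a plain function over numpy
arrays, so individual pieces (the focal loss, the stripper, the CV
splitters) are easy to lift into other projects.

## The method

**Preprocessing.** Grayscale conversion, a 3×3 median filter
`f(x,y) = median{g(s,t) : (s,t) ∈ S_xy}`, then edge enhancement: the
response of the fixed zero-sum high-pass mask

```
 -1   2  -1
  0   0   0
  1  -2   1
```

is added back onto the image (applied as a correlation, replicated
borders, clipped to the declared intensity range). Before training, images
are standardized to zero mean and unit variance, `X̂ = (X − μ)/σ`.

**Skull stripping.** Otsu global threshold on a median-smoothed copy →
binary opening (radius 2) to detach the thin bright skull ring → largest
connected component → closing + hole filling → all pixels outside the
brain mask set to zero.

**Segmentation.** An encoder–decoder FCNN: three 3×3 convolution blocks
(64 filters, stride 1, pad 1, batch-norm + ReLU) with 2×2 max pooling
after the first two, two stride-2 transposed convolutions back to input
resolution, and a 1×1 softmax head. Training minimizes the focal loss

```
L = mean over pixels of  −(1 − p_t)^γ · l_t · ln p_t
```

with γ the focusing exponent, `l_t` inverse-class-frequency weights and
`p_t` the predicted probability of the pixel's true class, using Adam
(lr 0.001), minibatch 30, up to 20 epochs, shuffling each epoch, Glorot
initialization, and early stopping after the validation loss has exceeded
its running minimum ten consecutive checks.

**Postprocessing.** Global threshold τ on the tumor probability map, then
removal of connected components smaller than a minimum area.

**Classification.** A feature backbone with a replaced 2-way
dropout + dense head (freeze/fine-tune configurable). The bundled backbone
is a small scratch-trained inception-style network; any externally
pretrained feature extractor can be plugged in through the same protocol.

**Evaluation.** 70/10/20 splitting (half-up rounding), record-wise
(stratified) and subject-wise (grouped) 10-fold cross-validation, and
accuracy / sensitivity / specificity / precision / dice computed from 2×2
confusion counts, reported as percentages.

## Worked example

```python
from tumorseg import PipelineConfig, run_pipeline

arts = run_pipeline(PipelineConfig(seed=1, out_dir="runs/demo"))
print(f"held-out mean dice:      {arts['seg_mean_dice']:.3f}")
print(f"classifier accuracy (%): {arts['clf_metrics'].accuracy:.1f}")
```

prints, for the default desk-scale study (200 phantoms of 64×64 pixels,
Gaussian noise σ = 0.05, 70/10/20 split, 20 training epochs):

```
held-out mean dice:      0.877
classifier accuracy (%): 97.5
```

i.e. on the 40 held-out slices the predicted tumor masks overlap the true
masks with mean dice 0.88, and 39/40 slices are assigned the correct
tumor/normal label. `runs/demo/` then contains the training histories,
a metrics CSV, and a manifest with the fully resolved configuration and
seed. The same workflow is scriptable from the shell:

```bash
tumorseg generate --seed 1 --out runs/ds --n-images 20
tumorseg run-all --seed 1 --out runs/full
```

## Layout

```
src/tumorseg/
  phantom.py      seeded synthetic brain phantoms + ground truth
  preprocess.py   grayscale, median filter, edge enhancement, z-score
  skullstrip.py   threshold/morphology brain extraction
  nn/             numpy layer stack (conv, BN, pooling, Adam, ...)
  segnet.py       FCNN builder, focal loss, trainer, prediction
  postprocess.py  global threshold + small-region removal
  classify.py     backbone adaptation, transfer training, prediction
  evaluate.py     splits, k-fold CV, confusion matrices, metrics
  io.py           PNG/NIfTI readers and writers, dataset manifests
  pipeline.py     end-to-end orchestration + run manifests
  cli.py          `tumorseg` command-line interface
```

See `docs/methods.md` for the modeling choices, parameter meanings, and
known limitations.
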