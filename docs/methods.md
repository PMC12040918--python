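# Methods

## The problem and the model

`cxrseg` implements multi-structure semantic segmentation of chest-radiograph-like
grayscale images: given an image, predict a binary mask per anatomical class
(lungs, heart, clavicles) plus a background channel. The pipeline has three
stages.

**Edge enhancement.** Anatomical boundaries in radiographs are low-contrast;
the front end sharpens them before the network sees the image. Horizontal and
vertical gradients are estimated by correlating the image with a 3×3 kernel
pair,

```
g_x(i,j) = Σ_{u=-1..1} Σ_{v=-1..1} I(i+u, j+v) · k_x(u+1, v+1)
```

(and likewise `g_y`), with either the standard Sobel pair (±1/±2 weights) or
the Scharr pair (±3/±10 weights, better rotational symmetry). The sums are
correlations — no kernel flip. Edge strength is the per-pixel Euclidean norm
`g = sqrt(g_x² + g_y²)`. The magnitude is min-max normalized per image and
mixed into the image by a convex blend with weight `blend_weight` (default
0.5): weight 0 keeps the raw image, weight 1 feeds the pure edge map to the
network. The blend is a deliberate design choice: replacing the image with
the edge map discards absolute intensity, which the phantom experiments show
carries most of the class signal; the blend preserves both readings and the
two extremes remain reachable through one parameter.

Two optional artifact-suppression operators bracket the edge step. CLAHE
(contrast-limited adaptive histogram equalization) runs before it: the image
is tiled, each tile's 256-bin histogram is clipped at `clip` times the
uniform bin height with the excess redistributed evenly, and the per-tile
equalization mappings are blended bilinearly between tile centers. With one
tile and a non-binding clip the operator reduces exactly to global histogram
equalization, which is the identity the unit tests pin. Adaptive
thresholding runs after it, binarizing the edge magnitude against the local
`block×block` mean plus an offset (strict inequality, replicated borders).
No canonical values exist for the clip limit, tile count, block size or
offset; the defaults (2.0, 4, 11, 0.0) are ordinary starting points and are
plain configuration.

**Segmentation network.** A U-Net: `depth` encoder levels of two 3×3
convolutions + ReLU followed by 2×2 max pooling, filter counts doubling per
level from `base_filters`; a two-convolution bottleneck; a symmetric decoder
using nearest-neighbor upsampling, a channel-halving 3×3 convolution, and
skip concatenation; a final 1×1 projection. The output activation is an
independent sigmoid per channel rather than a softmax across channels, so
classes may overlap (the heart shadow lies inside the lung field) and
prediction is multi-label: each channel is thresholded independently at
`threshold` (default 0.5, strict inequality). The background channel of a
prediction comes from its own output channel; it is not recomputed as a
complement, so disagreement between channels is visible rather than hidden.

The network is implemented directly on numpy (im2col convolutions with
explicit backward passes, Adam updates); gradient correctness is verified
against central finite differences in the test suite. One caveat those
tests document: an exactly-zero pre-activation sits on the ReLU kink, where
the loss is not differentiable and finite differences are not meaningful,
so the checks perturb biases away from zero first.

**Loss, weights, schedule.** Class imbalance is severe by construction —
lungs ≫ heart ≫ clavicles by pixel count. Two mechanisms counter it. Class
weights are inversely proportional to pixel frequency: `f_c` is class `c`'s
share of all labeled pixels, raw weights `1/f_c` are rescaled to mean 1 so
the loss scale does not depend on the class count. A class absent from the
training masks is a hard error, not a silent infinity. The loss is a
per-channel binary focal loss under the sigmoid outputs,

```
FL = −α_c · (1 − p_t)^γ · log(p_t),    p_t = p if target=1 else 1−p,
```

averaged over all elements, with `α_c` the channel's class weight and
focusing parameter `γ = 2` by default. Probabilities are clamped to
`[1e−7, 1 − 1e−7]` before the log. The binary (per-channel) rather than
categorical form is forced by the overlapping-classes reading of the sigmoid
head. The learning rate follows a polynomial decay per epoch,

```
lr(step) = (lr_initial − lr_end) · (1 − step/decay_steps)^power + lr_end,
```

defaults `1e−3 / 1e−5 / power 1`, `decay_steps` equal to the epoch count so
the final epoch trains at `lr_end`; steps beyond `decay_steps` clamp.

## Data pipeline

Per-part masks (left/right lungs, left/right clavicles, heart) merge by
elementwise maximum into one channel per class; a background channel is
appended as the exact complement of the union of structures, and that
identity is re-enforced after every geometric transform. Images load from
8/16-bit PNG/TIFF rescaled to [0, 1]; masks binarize at half of full scale.
Resizing is bilinear for images and nearest-neighbor for masks (so masks
stay binary); coordinates are 0-based, row-major, origin top-left.

Augmentation adds exactly one rotated copy per sample, with the angle drawn
uniformly from [−5°, 5°] excluding exactly 0 (re-drawn on a zero hit), the
same angle applied to image and masks, black fill outside the original
support, and the angle recorded in the copy's metadata. Copies carry a
`source_id`, and the train/test split assigns every sample of a source group
to the same side — a leakage guard, since an image and its 3°-rotated twin
are not independent.

Splits and folds are seeded. The hold-out split targets
`round(test_fraction · n)` test samples; with strata, test slots are
allocated across strata by largest-remainder rounding, so each stratum's
share deviates from the target fraction by less than one sample. Because an
augmented group is indivisible, grouped datasets can deviate from the exact
total by up to the group size minus one. K-fold plans come from seeded
(optionally stratified) k-fold splitters with fold sizes balanced within
one. The stratification label for a segmentation corpus is genuinely
underdetermined — every image contains every class — so the package defaults
to quantile bins of the per-image clavicle pixel fraction (the smallest,
hardest class); any other label vector can be passed instead.

## Evaluation

Per class, the report carries pixel accuracy, Dice `2|S∩G|/(|S|+|G|)` and
Jaccard `|S∩G|/|S∪G|`, averaged over test images, along with the all-channel
pixel accuracy (accuracy including background is reported separately from
the per-class rows, since which variant "accuracy" denotes is ambiguous in
the field). Two masks that are both empty score Dice = Jaccard = 1: a
correct "nothing present" prediction is not penalized. The summary objective
is mean Dice plus mean Jaccard over the set, each image's D and J first
averaged over the three structure classes with background excluded —
including the dominant, trivially-correct background channel would inflate
the objective. The identity `J = D/(2 − D)` and the bound `J ≤ D` are
checked property-style in the tests.

Method comparison uses a two-sided paired t-test on per-image scores:
`t = mean(d)/(sd(d)/√n)` with sample standard deviation and `df = n − 1`,
p-values from the exact t distribution (fold counts are small, so a normal
approximation would be sloppy). Zero-variance differences raise an explicit
degenerate-case error instead of returning an infinite statistic.

## The phantom generator

Every stage is testable without external data via seeded synthetic phantoms
that copy the *statistical* layout of a posteroanterior chest film: two
large bright elliptical lung fields (full contrast gap over the background),
one medium heart ellipse low on the midline overlapping a lung at 0.75 of
the gap, and two thin tilted clavicle bars over the lung apices at half the
gap — the hardest, lowest-contrast class, as in real radiographs. Centers,
axes and angles get mild seeded jitter so augmentation and stratification
have variability to work with; additive Gaussian noise (default sd 0.05) is
clipped to [0, 1]. Identical specs are bit-identical; per-sample seeds in a
corpus derive from a `SeedSequence` keyed on (base seed, index).

What the phantoms do **not** emulate: anatomical texture (ribs, vasculature,
mediastinum), intensity gradients from beam hardening, pathology, or
inter-patient shape variation beyond ellipse jitter. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that it can recover
known geometry under noise and class imbalance at desk scale — not that it
reaches any particular accuracy on clinical radiographs.

## Problem sizes and numerical choices

The package's reference experiments run on one CPU: phantoms are 64×64, the
network depth 2 with 8 base filters, training 50 epochs on 32 images with 8
held out, and 2-fold cross-validation on 16 images. At these sizes a corpus
gives few optimizer steps per epoch, and large-batch Adam proved fragile —
depending on the initialization seed a whole class channel could collapse to
zero — so the default batch size is 1: single-image updates maximize step
count and were stable across every seed tried. Other defaults: He-normal
weight initialization seeded from the training seed; Adam β = (0.9, 0.999),
ε = 1e−8; min-max magnitude normalization maps a constant (zero-gradient)
image to an all-zero edge component; mask validation accepts only exact
{0, 1} values; the binarization threshold uses strict inequality, so a
probability exactly at the threshold maps to 0.

## Known limitations

- The numpy network is desk-scale machinery: fine at 64–128 px and depth ≤ 3,
  not a GPU substitute for 512×512 training.
- The heart channel, which overlaps the lungs and sits at intermediate
  contrast, converges less reliably than lungs or clavicles at the smallest
  training sizes; more epochs or images resolve it.
- Bit-exact reproducibility of training holds on one machine/BLAS; across
  BLAS implementations, floating-point reduction order may differ.
- CLAHE redistributes clipped histogram mass in a single pass, which can
  leave bins marginally above the clip limit; the effect is visually and
  numerically negligible and the equalization identities tested are exact.
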