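# cxrseg

Edge-enhanced U-Net segmentation of chest-radiograph-like images.

Segmenting anatomical structures in chest radiographs — lung fields, the
heart shadow, the clavicles — is a standard preprocessing step for computer-
aided diagnosis, and it is hard precisely where it matters: boundaries are
low-contrast and the classes are wildly imbalanced (lungs occupy orders of
magnitude more pixels than clavicles). `cxrseg` implements a pipeline for
this problem aimed at researchers who want a fully inspectable, CPU-sized
reference implementation:

1. **Edge enhancement** — Sobel or Scharr 3×3 gradient kernels give the edge
   magnitude g = √(g_x² + g_y²), which is normalized and blended into the
   image; optional CLAHE before and local-mean adaptive thresholding after
   suppress the noise the gradient operators amplify.
2. **Segmentation** — a U-Net (encoder/decoder with skip connections) with a
   per-channel sigmoid head, so overlapping structures are handled as
   multi-label prediction; trained with a class-weighted focal loss
   FL = −α_t (1 − p_t)^γ log p_t, α inversely proportional to class pixel
   frequency, under a polynomial learning-rate decay.
3. **Evaluation** — per-class accuracy, Dice D = 2|S∩G|/(|S|+|G|) and
   Jaccard J = |S∩G|/|S∪G|, the combined mean-Dice + mean-Jaccard objective,
   seeded 80:20 or stratified k-fold protocols, and paired t-tests between
   methods.

Everything is testable without clinical data: a seeded phantom generator
produces chest-like images (two lung ellipses, an overlapping heart ellipse,
two faint clavicle bars) with exact ground-truth masks and the same
class-imbalance structure as real corpora. The network is pure
numpy/scipy with hand-verified gradients; no deep-learning framework is
required. See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import cxrseg as cs
from cxrseg.edges import EnhanceOptions

train = cs.generate_dataset(32, cs.PhantomSpec(seed=1))      # 64x64 phantoms
held_out = cs.generate_dataset(8, cs.PhantomSpec(seed=2))

cfg = cs.TrainConfig(epochs=50, seed=1, enhance=EnhanceOptions(method="sobel"))
model, history = cs.train_model(train, cs.UNetSpec(depth=2, base_filters=8), cfg)
report = cs.evaluate_model(model, held_out)
print(report.per_class.round(4))
print("combined objective:", round(report.combined_objective, 4))
```

prints (a few minutes on one CPU):

```
            accuracy    dice  jaccard
class
lungs         0.9818  0.9677   0.9375
heart         0.9934  0.9561   0.9162
clavicles     0.9970  0.9188   0.8505
background    0.9850  0.9888   0.9778
combined objective: 1.8489
```

Reading: the model recovers the dominant lung fields at Dice 0.97 and even
the thin, half-contrast clavicle bars at Dice 0.92 from 32 training images;
the combined objective (mean Dice + mean Jaccard over structure classes,
maximum 2) summarizes overall overlap quality. The same pipeline is
available from the shell:

```sh
cxrseg synth --n 32 --seed 1 --out corpus/
cxrseg train --data corpus/manifest.csv --out run/
cxrseg eval --checkpoint run/checkpoint.npz --data corpus/manifest.csv --report run/report
cxrseg cv --data corpus/manifest.csv --k 2 --out run/cv/
```

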