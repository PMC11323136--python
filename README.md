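# sefunet

Multi-organ segmentation of abdominal CT with **SEF-UNet**: a U-shaped
encoder–decoder whose encoder stacks MetaFormer-style residual blocks with a
squeeze-and-excitation-gated depthwise-separable convolution as token mixer
(*SEFormer* blocks), and whose decoder is a cascade of depthwise upsampling
(*dCUP*) blocks. The package targets the standard 8-organ abdominal task
(spleen, right/left kidney, gallbladder, liver, stomach, aorta, pancreas +
background) on portal-venous CT, trained and evaluated slice-wise on axial
sections.

The whole network — forward pass, reverse-mode gradients, SGD training —
runs on a compact numpy autodiff core (`sefunet.autodiff`), so the package
has no deep-learning framework dependency.

## Model

Encoder stage *i* = one strided downsampling convolution (×4 stem, then ×2)
followed by *L<sub>i</sub>* SEFormer blocks at constant width *C<sub>i</sub>*:

```
X' = SESepConv(LN(X)) + X
Y  = X' + MLP(LN(X'))
SESepConv(X) = pw2( SE( dw( ReLU( pw1(X) ) ) ) )
SE(U) = sigmoid(W2 · ReLU(W1 · GAP(U))) ⊙ U
```

Defaults: depths [3, 3, 9, 3], dims [64, 128, 320, 512], giving feature maps
at 1/4 … 1/32 of the 224×224 input. Stages 1–3 feed skip connections; the
decoder applies four dCUP blocks (output channels [256, 128, 64, 16]):

```
Y = dw( ReLU( BN( conv3x3( cat(skip, up2(X)) ) ) ) )
```

and a 1×1 classifier + bilinear ×2 restores input resolution. The training
objective is the mean of pixel cross-entropy and batch soft-Dice,
`L = (L_CE + L_Dice) / 2`. Evaluation reports per-organ DSC and the pooled
symmetric 95th-percentile Hausdorff distance (HD95, mm) on 3-D stacked
predictions.

With the calibrated ratio defaults (mixer expansion 1.75, SE reduction 4,
MLP ratio 3.125, 5×5 encoder depthwise kernel) the default configuration has
**24.65 M** learnable parameters.

## Worked example

No patient data is needed: the phantom module writes paired NIfTI volumes
with 8 ellipsoidal "organs" (two pairs sharing a boundary) whose HU means
span beyond the [−125, 275] soft-tissue window.

```python
import numpy as np
from sefunet import (SEFUNetSegmenter, PhantomSpec, generate_phantom,
                     evaluate_case)
from sefunet.data import clip_normalize_hu, extract_axial_slices, resize_image

vol, lab = generate_phantom(PhantomSpec(seed=7))        # (24, 96, 96) case
norm = clip_normalize_hu(vol)                           # HU -> [0, 1]
pairs = extract_axial_slices(norm, lab)
X = np.stack([np.clip(resize_image(p.image, 96), 0, 1) for p in pairs])
y = np.stack([resize_image(p.label, 96, mode="label") for p in pairs])

est = SEFUNetSegmenter(dims=(16, 32, 64, 128), depths=(1, 1, 2, 1),
                       input_size=96, decoder_channels=(64, 32, 16, 16),
                       batch_size=4, epochs=10**6, max_iterations=1500,
                       learning_rate=0.03, augment=False, seed=7)
est.fit(X, y)
pred = est.predict_volume(vol)                          # 3-D label volume
case = evaluate_case(pred.labels, lab.labels, vol.spacing)
print(f"mean foreground DSC {case.mean_dsc:.3f}  "
      f"mean HD95 {case.mean_hd95:.2f} mm")
```

prints (after ~4 minutes of single-core training)

```
mean foreground DSC 0.969  mean HD95 0.75 mm
```

i.e. the reduced model fully recovers the case it was trained on — the
standard overfit sanity check for a segmentation pipeline.

The same flow is available from the shell:

```bash
sefunet make-phantom data/ --n-cases 4
sefunet train data/manifest.tsv --out-dir runs/demo --max-iterations 50
sefunet evaluate runs/demo/last.npz data/manifest.tsv --out results.tsv
sefunet summary          # parameter / MAC budget of the default model
```

`sefunet summary` prints `total 24.65 M params` and the MAC count at the
configured resolution. `sefunet evaluate` writes one row per test case plus
a cohort row (DSC %, HD95 mm, then the 8 organs).

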