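# rgbdet — dual-stream RGB-D fruit detection with attention fusion

Detecting fruit in orchards from colour images alone fails exactly where it
matters: under leaf/branch occlusion, night lighting and lens glare. A
registered depth camera sees through most of that — depth is indifferent to
illumination — but consumer depth maps bring their own pathology, rings of
invalid ("hollow") pixels at object silhouettes. `rgbdet` is a small,
self-contained toolkit for studying the *feature-level fusion* of such
aligned RGB-D pairs inside a dual-stream detector, built for researchers in
agricultural machine vision who want the fusion math executable and testable
on a laptop CPU, with no GPU, no framework and no external dataset.

The package runs on its own minimal NumPy autograd engine (`rgbdet.nn`), so
every equation below is a few dozen transparent lines you can step through.

## The two fusion blocks

**LGEM (local–global enhancement).** Given per-stage features
`RGB, Depth ∈ R^{b×c×h×w}`:

```
Local   = concat(RGB, Depth)                          ∈ R^{b×2c×h×w}
E_local = LN(Conv_{c/2→1}(ReLU(Conv_{c/2→c/2}(Conv_{2c→c/2}(Local))))) ⊕ Conv_{2c→1}(Local)
q,k,v   = Flatten(E_local)              # spatial positions as tokens
A       = softmax(q·kᵀ/√d_k)·v          # single-head self-attention
E_global= Conv_{1→1}(Upsample(A))       # Upsample = inverse of Flatten
RGB_E, Depth_E = RGB ⊗ E_global, Depth ⊗ E_global
```

A one-channel weight map distilled from the *mixed* modalities is globalised
by self-attention and multiplies both streams — depth structure repairs
light-polluted colour features.

**RFAM (rough–fine fusion).** Coarse stage: bidirectional cross-attention
(`Attention1 = softmax(q₁·k₂ᵀ/√d_k)·v₂` and vice versa) followed by two
independent bottleneck MLPs gives coarse-fused grids `RGB_R, Depth_R`. Fine
stage (coordinate attention): max-pool each grid along height and width into
directional profiles `(b,c,w,1)` and `(b,c,1,h)`, splice all four into one
vector of length `2w+2h`, transform with a shared MLP, split back (splice and
split are exact inverses for an identity MLP), then

```
Fused = RGB_R ⊛ RGB_w ⊛ RGB_h + Depth_R ⊛ Depth_w ⊛ Depth_h
```

with the profiles broadcast across their collapsed axes.

Around the blocks sits a configurable scaffold: one feature stack per
modality (strides 8/16/32), LGEM at every stage, RFAM fusing every stage, a
pooling-and-merge neck, anchor-free heads, an optional RGB auxiliary branch
(pass-through → linear channel splits → upsample-and-splice merges) for deep
supervision, and a tri-modal (RGB+Depth+IR) variant
`f = RFAM(RFAM(x,y), RFAM(x,z))`. The evaluation suite implements IoU
matching, precision/recall, all-point-interpolated AP, mAP50 and mAP50:95;
the synthetic generator fabricates aligned scenes with the four occlusion
classes (False/Leaf/Branch/Fruit), glare/dark corruption and boundary depth
voids, so everything is testable offline.

## Worked example

```python
import numpy as np
from rgbdet.lgem import LGEM, lgem_forward
from rgbdet.rfam import RFAM, rfam_forward

rng = np.random.default_rng(0)
rgb, depth = rng.normal(size=(1, 8, 16, 16)), rng.normal(size=(1, 8, 16, 16))
lgem = LGEM(channels=8, rng=np.random.default_rng(1))
rgb_e, depth_e = lgem_forward(lgem, rgb, depth)
fused = rfam_forward(RFAM(channels=8, rng=np.random.default_rng(2)), rgb_e, depth_e)
print(rgb_e.shape, fused.shape)
```

prints `(1, 8, 16, 16) (1, 8, 16, 16)` — both blocks preserve the feature
shape, so they drop into any stage of a dual-stream backbone. The
`examples/` directory holds one short narrative script per capability;
`examples/04_train_toy_detector.py` trains a tiny detector for 5 epochs on
16 synthetic scenes and prints the loss components per epoch (from 4.73 down
to 2.31) and the early validation mAP50.

There is also a thin CLI:

```
rgbdet generate --n 100 --out dataset --image-size 128 --seed 0
rgbdet train --data dataset --out runs/exp --epochs 20
rgbdet eval --checkpoint runs/exp/checkpoint.npz --data dataset --split val
rgbdet predict --checkpoint runs/exp/checkpoint.npz --rgb r.png --depth d.png
```

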