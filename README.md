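# sdhseg — boundary-aware segmentation losses for binary tumor masks

`sdhseg` is a toolkit for training and evaluating binary (tumor vs.
background) segmentation networks with a **sub-differentiable averaged
Hausdorff loss**: the bidirectional mean of nearest-neighbour Euclidean
distances between the *boundary point sets* of the predicted and
ground-truth masks,

```
H(P, G) = (1/|P|) Σᵢ min_j ‖pᵢ − gⱼ‖₂  +  (1/|G|) Σⱼ min_i ‖gⱼ − pᵢ‖₂ ,
```

combined with pixel-wise binary cross-entropy as
`L = λ₁·L_BCE + λ₂·L_SDHL` (defaults λ₁ = 0.6, λ₂ = 0.4). Plain pixel
losses are nearly blind to *where* a segmentation errs; on data where
lesions occupy a few percent of the frame and have fuzzy margins, the
boundary term explicitly penalises contour misalignment while BCE secures
region accuracy. Subgradients of H exist everywhere (nearest-neighbour
ties are broken deterministically; coincident points get the zero
subgradient), and training uses a differentiable pixel-grid surrogate that
is *exactly* equal to H on hard masks — see `docs/methods.md`.

The package is aimed at method developers who want a fully inspectable,
CPU-scale reference implementation: every piece — boundary geometry,
loss values and subgradients, the training surrogate, UNet-family models
(UNet, Attention UNet, UNet++), Adam, seven mask metrics (accuracy,
precision, recall, Dice, F1, IoU, MCC) and a synthetic tumor-phantom
generator — is pure numpy/scipy, deterministic under a seed, and tested
against independent brute-force oracles. No GPU, no downloads.

## Worked example

```python
import numpy as np
from sdhseg import UNetSegmenter, generate_dataset, sdhl_mask_pair

data = generate_dataset(n=200, seed=123)          # 64x64 phantoms, 34.9% with lesions
est = UNetSegmenter(architecture="attention_unet", depth=3, base_channels=8,
                    loss="sdhl+bce", lambda1=0.6, lambda2=0.4,
                    epochs=30, seed=1)
est.fit(data.train.images, data.train.masks,
        validation=(data.val.images, data.val.masks))

preds = est.predict(data.test.images)
dice = est.score(data.test.images, data.test.masks)
bd = np.mean([sdhl_mask_pair(preds[i], data.test.masks[i]).total
              for i in range(len(preds))])
print(f"held-out mean Dice = {dice:.4f}")
print(f"mean boundary distance = {bd:.3f} px")
```

Output on one CPU core (a few minutes):

```
held-out mean Dice = 0.9645
mean boundary distance = 0.401 px
```

Dice is the per-image overlap score averaged over the 40 held-out
phantoms (an image with no lesion and no detection counts as 1.0); the
boundary distance is H(P, G) between predicted and true mask boundaries
in pixels — 0 means the contours coincide exactly.

The point-set loss itself is a two-liner:

```python
from sdhseg import extract_boundary, sdhl_point_set
bd = sdhl_point_set(extract_boundary(pred_mask), extract_boundary(gt_mask))
print(bd.term_pg, bd.term_gp, bd.total)   # directed terms + total, in px
```

## Command line

```bash
sdhseg generate --n 200 --seed 7 --out data/        # phantom dataset + manifest
sdhseg train --data data/ --out run/ --seed 1       # train, write history/checkpoint/metrics
sdhseg loss pred.png gt.png                         # boundary loss + Dice/IoU of two masks
sdhseg ablate --data data/ --out ab/ --seed 1       # HDL / BCE / HDL+BCE / SDHL / SDHL+BCE
sdhseg sweep --data data/ --out sw/ --grid-step 0.5 # (λ1, λ2) grid search
```

Every command is reproducible under `--seed` and writes a
`run_manifest.json` recording the effective configuration.

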