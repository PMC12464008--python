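# phenocloud

Stem–leaf segmentation and automated phenotypic trait measurement for
field-crop point clouds, built around tobacco-scale plants.

High-throughput phenotyping pipelines reconstruct individual plants as 3D
point clouds (e.g. from UAV photogrammetry) and then need two things: a
per-point semantic segmentation into **stem** and **leaf**, and the
**phenotypic parameters** that agronomists actually record — plant height,
leaf length, leaf width, leaf number, and internode length. `phenocloud`
implements that pipeline end to end for researchers working with individual
plant clouds, together with a synthetic-plant generator that makes every
stage testable without field data.

## What is inside

* **Synthetic plants** (`phenocloud.synthetic`) — tobacco-like plants: a
  vertical cylindrical stem carrying 4–10 planar elliptical leaves at
  increasing heights, with per-point semantic labels, per-leaf instance ids,
  exact ground-truth traits, and optional ground plane / outlier noise.
* **Preprocessing** (`phenocloud.preprocess`) — RANSAC ground-plane removal
  (distance threshold 0.2 m, 3-point fits, 500 iterations), statistical
  outlier filtering (50 neighbours, 1.0 σ), and uniform stride downsampling
  (rate 2).
* **Segmentation network** (`phenocloud.network`, `phenocloud.model`) — a
  hierarchical encoder–decoder on raw coordinates. Each set-abstraction (SA)
  layer halves the centre count with farthest point sampling, groups K = 16
  nearest neighbours, and augments the shared-MLP feature lift with:
  * **Local Spatial Encoding (LSE)**: per neighbour, the concatenation
    `[p_i ⊕ p_ik ⊕ (p_i − p_ik) ⊕ d(p_i, p_ik)]` (a 10-vector) is mapped by a
    shared MLP and concatenated with the neighbour's feature;
  * **Density-Aware Pooling (DAP)**: the neighbourhood density
    `D_i = (1/K) Σ_k 1/(d(p_i, p_ik) + ε)` is min–max normalized; centres
    denser than their neighbourhood mean take max pooling as the primary
    aggregate, sparser centres take attention pooling
    `F_att = Σ_k softmax(g(a_ik)) · a_ik`, and the two branch outputs are
    concatenated and fused by an MLP (`F_i = MLP(F_att ⊕ F_max)`).
  Feature-propagation (FP) layers interpolate features back to full
  resolution with inverse-distance weights. Both LSE and DAP can be switched
  off, which reduces the SA layer to a plain grouped-MLP + max-pool baseline
  for ablations.
* **Trait extraction** (`phenocloud.traits`) — plant height
  `H = Z_max − Z_min`; leaf instances by Euclidean-connectivity clustering of
  leaf points; leaf length/width as the sides of the minimum-area bounding
  rectangle of each leaf's PCA-plane projection; internode length as the
  vertical distance between the bases of the upper and middle leaves.
* **Evaluation** (`phenocloud.metrics`) — OA / per-class IoU / mIoU from the
  confusion matrix, and R² / RMSE for trait agreement.
* **CLI** (`phenocloud`) — `simulate`, `preprocess`, `train`, `segment`,
  `traits`, `evaluate` subcommands wiring the modules into one workflow.

The network and its training loop are implemented in numpy on a small
reverse-mode autodiff engine (`phenocloud.autograd`); no GPU or deep-learning
framework is required.

## Worked example

```python
import numpy as np
import phenocloud as pc
from phenocloud.network import NetConfig

# four labeled synthetic plants, resampled to 1024 points each
plants = pc.make_field(4, seed=3, noise_sigma=0.0)
clouds = [cloud for cloud, record in plants]

model = pc.StemLeafSegmenter(
    clouds,
    train_config=pc.TrainConfig(max_epoch=60, batch_size=1, num_points=1024,
                                k=16, learning_rate=2e-3, lr_step=20, seed=0),
    net_config=NetConfig(num_points=1024, k=16,
                         sa_channels=((24, 48), (48, 96), (96, 192)),
                         fp_channels=(96, 96), head_channels=128, seed=0),
)
result = model.fit()
print(f"best training OA: {max(h['train_oa'] for h in result.history):.2f}%")
ev = result.evaluate(clouds, seed=5)
print(f"OA {ev['oa']:.2f}%  stem IoU {ev['iou_per_class'][0]:.2f}%  "
      f"leaf IoU {ev['iou_per_class'][1]:.2f}%  mIoU {ev['miou']:.2f}%")

# segment a cloud and measure it
pred = result.predict(clouds[0], seed=0)
traits = pc.extract_traits(pred, min_cluster_size=15)
print(f"plant height: {traits.plant_height:.1f} cm "
      f"(ground truth {plants[0][1].plant_height:.1f} cm)")
```

Output (CPU, a few minutes):

```
best training OA: 99.51%
OA 97.31%  stem IoU 80.84%  leaf IoU 96.97%  mIoU 88.90%
plant height: 94.6 cm (ground truth 97.9 cm)
```

The first line is the share of the 4 × 1024 training points whose stem/leaf
label the fitted network reproduces at its best epoch. The second line
re-evaluates the model on independently resampled points of the same plants
(stem IoU is the harder class: stems carry ~8× fewer points than leaves).
The last line measures plant height as the z-range of the segmented,
metric-scale cloud; the ~3 cm shortfall comes from resampling the cloud to
the network's 1024-point input before measuring.

The same workflow from the shell:

```bash
phenocloud simulate --n 4 --seed 1 --out-dir field/
phenocloud preprocess field/*.ply --out-dir clean/ --skip-ground
phenocloud train clean/*.ply --checkpoint model.json --num-points 1024 \
    --sa-channels "24,48;48,96;96,192" --batch-size 1 --epochs 60
phenocloud segment clean/*.ply --checkpoint model.json --out-dir segmented/
phenocloud traits segmented/*.ply --out traits.csv
phenocloud evaluate --pred traits.csv --truth field/truth.csv
```

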