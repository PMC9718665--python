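# cellseg

Desk-scale cellular instance segmentation: flow-field mask prediction, a
style-routed model zoo, fine-tuning from pretrained weights, and a
human-in-the-loop (HITL) annotation/retraining loop — all runnable end to
end on a laptop CPU from fully synthetic data.

## The problem

Automated cell segmentation faces two coupled obstacles. First, new image
types (different tissues, microscopes, stains) break models trained on
other data. Second, even on the *same* images, human annotators disagree
systematically — whether to label nuclei without cytoplasm, whether to
trace diffuse processes, how far outside the membrane to draw — so there
are many equally valid "ground truths", and a single universal model
cannot satisfy them all. This package implements, at desk scale, the
machinery that addresses both: adapt a pretrained flow-field segmentation
model to a new image type and annotation style with very few labelled
ROI, either offline or interactively.

## The model

A residual U-net maps a 1–2 channel image to three maps: the probability
p(x) of pixel x being inside a cell, and a unit vector field
(∇y, ∇x)(x) pointing toward the centre of the cell containing x. Masks
are recovered by advecting every pixel with p > 0.5 along the flow field;
pixels whose trajectories converge to the same sink form one ROI, and ROI
whose predicted flows disagree with the flows recomputed from their own
shape (mean squared discrepancy > 0.4) are rejected. Training targets are
built by heat diffusion from each ROI's median-coordinate centre.

The global average pool of the deepest feature maps is a 256-dimensional
(desk scale: 16-dimensional) **style vector** describing the image; it is
broadcast back into the decoder as a per-level channel bias, and it routes
images to models: style vectors of a corpus are clustered (K-NN graph +
Leiden, resolution 0.45), one specialist model is trained per cluster, and
a new image goes to the cluster of its 5 nearest neighbours ("suggestion
mode").

Segmentation quality is average precision at an IoU threshold,
AP = TP / (TP + FP + FN), after optimal one-to-one mask matching,
averaged over images; the headline threshold is 0.5.

## Worked example

Train a tiny model on synthetic scenes, segment a held-out scene, and
score it:

```python
import numpy as np
from cellseg import (SceneConfig, generate_scene, NetConfig, TrainConfig,
                     train_model, segment_image, average_precision)

scenes = [generate_scene(SceneConfig(canvas=(64, 64), n_cells=7,
                                     diameter_mean=12, seed=s))
          for s in range(4)]
res = train_model("scratch", scenes, TrainConfig.online(epochs=100, seed=0),
                  net_config=NetConfig(n_levels=2, base_channels=8, seed=0))
test = generate_scene(SceneConfig(canvas=(64, 64), n_cells=7,
                                  diameter_mean=12, seed=100))
masks = segment_image(res.net, test)
ap = average_precision(masks, test.labels, thresholds=[0.5])[0]
print(f"found {masks.max()} of {test.n_rois} cells, AP@0.5 = {ap:.2f}")
```

```
found 7 of 7 cells, AP@0.5 = 1.00
```

The training log (`res.log`) holds per-epoch learning rate and loss; the
final loss here is ≈ 0.17 after the 100-epoch online schedule (linear
warmup to lr 0.1, no annealing). The printed AP means every one of the 7
reconstructed masks matched its true cell at IoU ≥ 0.5.

The same pieces scale up through the CLI:

```bash
cellseg simulate --n-images 4 --seed 0 --out scenes/
cellseg train --mode online --manifest scenes/manifest.json --out model.npz
cellseg flows make scenes/lab_0.tif flows.tif
cellseg eval --pred preds/ --truth truths/ --thresholds 0.5:0.9:0.05
```

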