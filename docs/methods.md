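# Methods

`cellseg` is a desk-scale implementation of flow-field cellular instance
segmentation with a style-routed model zoo, fine-tuning from pretrained
weights, and a human-in-the-loop (HITL) annotation/retraining loop. This
note records the model, the numerical choices, what the synthetic data do
and do not emulate, and the scaled-down conditions under which the test
suite and `scripts/acceptance.py` run everything.

## Flow-field representation

An instance label map (0 = background, positive integers = ROI) is turned
into three per-pixel regression targets: the probability of being inside a
cell and the (y, x) components of a unit vector field pointing toward each
ROI's centre. The field is constructed by heat diffusion: within each
ROI's padded bounding box, heat is injected at the ROI centre and averaged
over the 4-neighbourhood restricted to the ROI for `2 × max(bbox height,
bbox width)` iterations; the flows are the unit-normalised gradient of
`log1p` of the temperature field.

Two numerical choices matter here:

* **Centre definition.** The centre is the per-axis median coordinate.
  When a median lands on a half-integer, the heat source is split
  bilinearly over the adjacent in-ROI pixels rather than snapped to one of
  them; this keeps the construction exactly equivariant under flips and
  90° rotations (a snapped centre breaks ties arbitrarily, which shows up
  as sign flips near the symmetry axis of even-sized ROI). If no
  bilinear-weighted pixel lies inside the ROI (thin crescents), the source
  snaps to the nearest in-ROI pixel.
* **Gradient floor.** Gradient magnitudes below 1e-6 are treated as zero
  before unit normalisation; at the centre of a symmetric ROI the
  "gradient" is float summation noise, and normalising it would turn noise
  into a full-length vector.

Reconstruction (`follow_flows`) advects every pixel whose inside
probability exceeds 0.5 along the bilinearly interpolated flow field for
200 Euler steps of 1 px, clamped to the canvas. Trajectory endpoints are
rounded to the grid and single-linkage clustered at a 2.5 px merge radius
(KD-tree + connected components); each cluster is one ROI, and ROI smaller
than 15 px are dropped. The round trip masks→flows→masks reaches mean
per-ROI IoU ≈ 1.0 on convex-cell scenes, which is the contract the rest of
the package relies on; numeric agreement with any other implementation of
the same idea is *not* a goal.

Quality control: for each reconstructed ROI the flows are recomputed from
its own shape and compared with the predicted flows inside it (mean
squared difference per component, averaged over pixels and the two
components). Self-consistent flows score ≈ 0, independent random unit
flows score ≈ 1; ROI above the threshold 0.4 are rejected. The threshold
is interpreted on this implementation's own scale, calibrated so the two
regimes sit far on either side of it while the slightly imperfect flows
of a well-trained network stay below it.

## Network

A residual U-net sized by `(n_levels, base_channels)` with channel count
doubling per level. Defaults are 4 levels × 32 channels (deepest level
256); all desk experiments use 2 levels × 8 channels on 48–64 px tiles.
Three 1×1-convolution outputs: inside-cell logit and the two flow
components. The **style vector** is the global average pool of the deepest
feature maps, L2-normalised; with `broadcast_style=True` (default) one
learned linear projection per decoder level turns it into a per-channel
bias added to the upsampling path, letting one network modulate its output
style per image. `broadcast_style=False` computes the vector but does not
inject it (the ablation arm). The exact wiring of the broadcast is a
design choice; a per-level additive channel bias is the simplest wiring
that makes the ablation meaningful.

The network and its training run on a small handwritten numpy reverse-mode
autodiff (`cellseg.nn`): conv2d via im2col, batch norm with full backward,
leaky ReLU (slope 0.05), max-pool/nearest-upsample, float32 throughout.
Gradients were verified against central finite differences. Two stability
choices interact with the large scheduled learning rates: the leaky (not
plain) rectifier, and clipping the global gradient norm at 4.0
(`TrainConfig.max_grad_norm`); without them a 0.1–0.2 peak learning rate
can kill most units in the first few epochs of a tiny network.

Inputs are normalised per channel by rescaling the 1st–99th percentile
range to [0, 1]. Images are reflect-padded to a multiple of
`2**n_levels` for the forward pass and cropped back.

## Training

Loss = 5 × MSE(flow components) + BCE(inside logit). The weight 5
compensates for flows being unit-scale targets over a minority of pixels;
both weights are config. Optimiser is SGD with momentum 0.9 and weight
decay (skipped for biases and batch-norm parameters).

Schedules (`TrainConfig` presets):

| preset | epochs | weight decay | peak lr | anneal |
|---|---|---|---|---|
| offline | 300 | 1e-4 | 0.1 | ×0.5 every 5 epochs after 250 |
| online | 100 | 1e-4 | 0.1 | none |
| generalist | 500 | 1e-5 | 0.2 | ×0.5 every 10 epochs after 400 |

All have a 10-epoch linear warmup from 0. Epochs resample the image list
with replacement up to a minimum of 8 images and then take batches of 8;
an optional per-image weight vector implements equal-cluster sampling for
the generalist baseline. Images with fewer than 5 ROI are excluded before
training (`filter_min_rois`).

Augmentation applies one geometric transform consistently to image, labels
and flows — flips, rotation (uniform 0–360°; exact array rotation at
multiples of 90°), scale jitter 0.75–1.25, crop, ±10% intensity — with the
flow *vectors* rotated along with the frame and re-normalised inside ROI
after interpolation.

## Synthetic scenes and annotation styles

`generate_scene` places non-overlapping blobby/elliptical/disk cells by
rejection sampling (packing requests above 0.9 are refused), renders flat,
granular or membrane-bright cytoplasm textures, an optional nucleus
channel, and additive Gaussian noise. Orphan nuclei — nuclei with no
cytoplasm signal — are extra truth ROI rendered only in the nucleus
channel. `apply_style` then produces what a particular annotator would
have drawn: drop orphan nuclei, bias boundaries outward/inward (outward
growth stops at collisions, so ROI never merge), skip crowded
neighbourhoods, skip dim cells. The same scene under two styles yields
conflicting but individually valid ground truths.

What this emulates: object density, size distributions, texture contrast
between image types, channel structure, and — centrally — annotation-style
conflicts. What it does not: optics (no PSF), realistic noise models,
overlapping cells (overlap handling is exercised separately through
`remove_overlaps` on synthetic overlapping pixel sets), out-of-focus
content, or the sheer visual diversity of real corpora. Passing tests
therefore demonstrate the *machinery* — flow construction and inversion,
metric correctness, routing, the economics of HITL — on images easy enough
for a tiny network, not segmentation accuracy on real microscopy.

## Dataset-preparation operators

* `remove_overlaps`: overlap fractions are computed on the original ROI
  pixel sets, so the removal rule (drop ROI with > 75% of pixels shared)
  is independent of the subsequent reassignment of contested pixels to the
  nearest surviving centroid (ties to the lower ROI index).
* `enhance_contrast`: `(I − G·I)/(G·I)` with Gaussian σ = 30 px. "Width"
  is interpreted as σ (not FWHM); the denominator is floored at
  1e-6 × max(I).
* `split_quarters`: floor-halves each axis, remainder to the last tile,
  per-tile ids re-indexed consecutively.
* Label maps are dense integer arrays; files are 16-bit PNG/TIFF with a
  bit-exact round trip for ids ≤ 65535.

## Evaluation

AP = TP/(TP+FP+FN) after one-to-one matching at an IoU threshold, averaged
unweighted over images; thresholds default to 0.5…0.9 in steps of 0.05,
with 0.5 the headline. Matching is the *optimal* assignment maximising
total matched IoU (Hungarian), with a greedy mode for comparison; on
instances without contested best matches the two agree, and the optimal
form is asserted equal to exhaustive enumeration on small instances.
Empty-truth/empty-prediction images score 1.0; empty truth with
predictions scores 0.0. The within-annotator bound un-mirrors the second
annotation pass before scoring. There are no per-ROI confidence scores
anywhere (this AP is not the COCO variant).

## Model zoo

Style vectors of a reference corpus are clustered by a Euclidean K-NN
graph (default 100 neighbours, capped at n−1 for small sets) partitioned
with Leiden at resolution 0.45, seeded and deterministic. Routing is a
5-NN majority vote among member vectors on L2-normalised styles
(normalisation stabilises distances; chosen since raw-versus-normalised is
not determined by the protocol), ties to the lower cluster id. One
specialist is trained per cluster; the generalist baseline trains on all
images with clusters sampled at equal probability.

## HITL loop

Each round: segment the next image, simulate the annotator (keep
predictions matching truth at IoU ≥ 0.5; copy every other truth ROI
verbatim — the manual work; delete unmatched predictions; on pixel
conflicts the manual stroke wins), retrain on all corrected images so far
with the online schedule, re-initialised each round from the original
pretrained checkpoint so rounds stay comparable (chained warm-starting
exists behind the config but is not the default). Spurious predictions are
deleted because an unmatched prediction is by definition incorrectly
segmented under the annotator's style. The offline baseline annotates
every ROI by hand and trains once with the offline schedule. The simulated
annotator is idealised: perfectly consistent, zero intra-annotator noise.

## Desk-scale experiment conditions

Fixed in `cellseg.experiments` and shared by the test suite and the
acceptance script (the tests use 5 seeds; the script uses 2 for the
training-heavy comparisons):

* Architecture 2 levels × 8 channels; training crop 48 px; scenes 64–96 px.
* Transfer: pretrain on 8 domain-A scenes (6 cells/scene, ⌀14 px,
  granular; online schedule, 100 epochs), then fine-tune vs scratch on 2
  domain-B scenes (10 cells, ⌀11 px, flat) for 60 online epochs each,
  AP@0.5 on 4 held-out domain-B scenes.
* HITL: the pretrained model's corpus never labels orphan nuclei; the HITL
  images (96 px, 20 cells + 30% orphan nuclei) do, so round 1 requires
  real manual work. The target domain is deliberately heterogeneous —
  texture, object size and noise level vary image to image — because a
  homogeneous domain is absorbed after a single corrected image and the
  per-round manual counts collapse to zero immediately; with a varied
  domain the counts decline over several rounds, which is the adaptation
  dynamic the experiment measures. 4 rounds, 60-epoch online retrains,
  100-epoch offline baseline.
* Ensemble: two-style benchmark (8 train + 3 test per class), style
  vectors from a deterministically initialised network, Leiden at 0.45,
  70-epoch generalist-structure schedule at peak 0.1 (the 0.2 peak of the
  full-scale preset is unstable for this tiny network; the preset default
  remains 0.2). The ablation arm rebuilds the whole pipeline with
  `broadcast_style=False`.
* Routing: 5-NN suggestion mode, 50 held-out images, accuracy against the
  generating class of each image.

## Known limitations

* The numpy network is CPU-only and small; nothing here speaks to
  full-scale segmentation accuracy.
* `remove_overlaps` reassignment is exact but quadratic in contested
  pixels; fine for annotation-scale overlaps, not for pathological input.
* Leiden at a fixed resolution on very few samples (n < ~20) is sensitive
  to the neighbour count; the capped K-NN graph can become complete and
  merge planted clusters, which is why small-set experiments use 5
  neighbours.
* The simulated annotator never makes mistakes, so HITL results bound the
  best case of the loop's annotation economics.
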