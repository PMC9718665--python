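"""SGD training schedules, epoch sampling, augmentation and the train loop.

Three schedule presets are used throughout:

* offline   — 300 epochs, batch 8, weight decay 1e-4, peak learning rate
  0.1 with a 10-epoch linear warmup, halved every 5 epochs after epoch 250.
* online    — 100 epochs, same warmup and peak, but *no* annealing: the
  short human-in-the-loop retraining schedule.
* generalist — 500 epochs, weight decay 1e-5, peak 0.2, halved every 10
  epochs after epoch 400 (used to train style-extraction and ensemble
  baselines from scratch).

Epochs resample the image list with replacement up to a minimum of eight
images, then take batches of eight. Images with fewer than five ROI are
expected to have been filtered out beforehand (:func:`dataio.filter_min_rois`).

The loss is a weighted sum of mean-squared error on the two flow
components (default weight 5 — flows are unit vectors, so they need
upweighting against the inside-cell binary cross-entropy to train at a
comparable rate) and binary cross-entropy on the inside-cell logit.
Gradients are clipped to a global norm (``max_grad_norm``) so the large
peak learning rates of the schedules do not kill units early in training.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import rescale as sk_rescale
from skimage.transform import rotate as sk_rotate

from . import nn
from .nn import autograd as ag
from .dataio import LabeledImage
from .flow import FlowTarget, masks_to_flows
from .network import FlowStyleNet, NetConfig, build_network, normalize_percentile

__all__ = [
    "TrainConfig",
    "AugmentConfig",
    "TrainingError",
    "TrainResult",
    "lr_schedule",
    "make_epoch",
    "augment",
    "apply_transform",
    "draw_transform",
    "train_model",
]


class TrainingError(RuntimeError):
    """Raised on divergence; carries the epoch index in the message."""


@dataclass
class TrainConfig:
    """Optimisation schedule. Presets: offline / online / generalist."""

    mode: str = "offline"
    epochs: int = 300
    batch_size: int = 8
    weight_decay: float = 1e-4
    peak_lr: float = 0.1
    warmup_epochs: int = 10
    anneal_start: int | None = 250  # epoch after which halving begins
    anneal_halving_period: int = 5
    min_images_per_epoch: int = 8
    momentum: float = 0.9
    max_grad_norm: float = 4.0
    flow_loss_weight: float = 5.0
    prob_loss_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("offline", "online", "generalist"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.epochs < self.warmup_epochs:
            raise ValueError("epochs must be at least warmup_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")

    @classmethod
    def offline(cls, **kw) -> "TrainConfig":
        return cls(mode="offline", **kw)

    @classmethod
    def online(cls, **kw) -> "TrainConfig":
        kw.setdefault("epochs", 100)
        kw.setdefault("anneal_start", None)
        return cls(mode="online", **kw)

    @classmethod
    def generalist(cls, **kw) -> "TrainConfig":
        kw.setdefault("epochs", 500)
        kw.setdefault("weight_decay", 1e-5)
        kw.setdefault("peak_lr", 0.2)
        kw.setdefault("anneal_start", 400)
        kw.setdefault("anneal_halving_period", 10)
        return cls(mode="generalist", **kw)


@dataclass
class AugmentConfig:
    """Geometric + photometric augmentation ranges.

    The identical geometric transform is applied to image, labels and
    flow maps, with the flow *vectors* rotated along with the frame.
    """

    rotate: bool = True
    scale_range: tuple[float, float] = (0.75, 1.25)
    flips: bool = True
    crop: int = 64
    intensity_jitter: float = 0.10

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if not (0.5 <= lo <= hi <= 2.0):
            raise ValueError("scale_range must lie within [0.5, 2]")


def lr_schedule(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate at a given epoch index.

    Linear warmup from 0 to ``peak_lr`` over the first ``warmup_epochs``,
    a plateau at ``peak_lr``, then (unless ``anneal_start`` is None, as in
    online mode) halving every ``anneal_halving_period`` epochs once the
    epoch index passes ``anneal_start``.
    """
    if not 0 <= epoch < cfg.epochs:
        raise IndexError(f"epoch {epoch} outside [0, {cfg.epochs})")
    if epoch < cfg.warmup_epochs:
        return cfg.peak_lr * (epoch + 1) / cfg.warmup_epochs
    if cfg.anneal_start is None or epoch <= cfg.anneal_start:
        return cfg.peak_lr
    n_halvings = 1 + (epoch - cfg.anneal_start - 1) // cfg.anneal_halving_period
    return cfg.peak_lr * 0.5**n_halvings


def make_epoch(
    n_images: int,
    cfg: TrainConfig,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Ordered batches of image indices for one epoch.

    If fewer than ``min_images_per_epoch`` images are available the list is
    resampled with replacement up to that minimum; otherwise the epoch is a
    permutation (or a weighted resample when ``weights`` is given, used for
    generalist training that samples style clusters with equal
    probability). Batches are consecutive groups of ``batch_size``.
    """
    if n_images < 1:
        raise ValueError("training set is empty")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        n_draw = max(n_images, cfg.min_images_per_epoch)
        order = rng.choice(n_images, size=n_draw, replace=True, p=w)
    elif n_images < cfg.min_images_per_epoch:
        order = rng.choice(n_images, size=cfg.min_images_per_epoch, replace=True)
    else:
        order = rng.permutation(n_images)
    return [
        order[i : i + cfg.batch_size] for i in range(0, len(order), cfg.batch_size)
    ]


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class TransformParams:
    angle: float = 0.0
    scale: float = 1.0
    flip_h: bool = False
    flip_v: bool = False
    crop: int | None = None
    crop_frac: tuple[float, float] = (0.0, 0.0)  # fractional top-left offset
    intensity: float = 1.0


def draw_transform(cfg: AugmentConfig, rng: np.random.Generator) -> TransformParams:
    return TransformParams(
        angle=float(rng.uniform(0.0, 360.0)) if cfg.rotate else 0.0,
        scale=float(rng.uniform(*cfg.scale_range)),
        flip_h=bool(rng.integers(2)) if cfg.flips else False,
        flip_v=bool(rng.integers(2)) if cfg.flips else False,
        crop=cfg.crop,
        crop_frac=(float(rng.random()), float(rng.random())),
        intensity=1.0 + float(rng.uniform(-1, 1)) * cfg.intensity_jitter,
    )


def apply_transform(
    pixels: np.ndarray,
    labels: np.ndarray,
    flows: FlowTarget,
    p: TransformParams,
) -> tuple[np.ndarray, np.ndarray, FlowTarget]:
    """Apply one geometric+photometric transform consistently.

    Flow vector components are rotated with the frame; exact multiples of
    90 degrees take a lossless array-rotation path. After warping, flows
    are re-normalised to unit length inside ROI and zeroed outside.
    """
    pix = pixels[None] if pixels.ndim == 2 else pixels
    pix = pix.astype(np.float32).copy()
    lab = labels.copy()
    fy, fx = flows.flow_y.astype(np.float32), flows.flow_x.astype(np.float32)

    if p.flip_h:  # left-right
        pix = pix[..., ::-1]
        lab = lab[:, ::-1]
        fy, fx = fy[:, ::-1], -fx[:, ::-1]
    if p.flip_v:  # up-down
        pix = pix[..., ::-1, :]
        lab = lab[::-1]
        fy, fx = -fy[::-1], fx[::-1]

    angle = p.angle % 360.0
    if angle:
        if angle % 90.0 == 0.0:
            k = int(angle // 90)
            pix = np.rot90(pix, k, axes=(-2, -1))
            lab = np.rot90(lab, k)
            for _ in range(k):
                # one 90-degree frame rotation maps (dy, dx) -> (-dx, dy)
                fy, fx = np.rot90(fy), np.rot90(fx)
                fy, fx = -fx, fy
        else:
            rad = np.deg2rad(angle)
            pix = np.stack(
                [sk_rotate(c, angle, order=1, preserve_range=True) for c in pix]
            ).astype(np.float32)
            lab = sk_rotate(
                lab, angle, order=0, preserve_range=True
            ).astype(lab.dtype)
            ry = sk_rotate(fy, angle, order=1, preserve_range=True)
            rx = sk_rotate(fx, angle, order=1, preserve_range=True)
            # rotate the vectors with the frame (array coords, y down)
            fy = (np.cos(rad) * ry - np.sin(rad) * rx).astype(np.float32)
            fx = (np.sin(rad) * ry + np.cos(rad) * rx).astype(np.float32)

    if p.scale != 1.0:
        pix = np.stack(
            [sk_rescale(c, p.scale, order=1, anti_aliasing=p.scale < 1) for c in pix]
        ).astype(np.float32)
        lab = sk_rescale(
            lab, p.scale, order=0, preserve_range=True, anti_aliasing=False
        ).astype(lab.dtype)
        fy = sk_rescale(fy, p.scale, order=1).astype(np.float32)
        fx = sk_rescale(fx, p.scale, order=1).astype(np.float32)

    if p.crop:
        pix, lab, fy, fx = _crop_or_pad(pix, lab, fy, fx, p.crop, p.crop_frac)

    inside = lab > 0
    norm = np.sqrt(fy**2 + fx**2)
    norm[norm < 1e-6] = 1.0
    fy = np.where(inside, fy / norm, 0.0).astype(np.float32)
    fx = np.where(inside, fx / norm, 0.0).astype(np.float32)

    pix = pix * p.intensity
    if pixels.ndim == 2:
        pix = pix[0]
    return pix, lab, FlowTarget(fy, fx, inside.astype(np.float32))


def _crop_or_pad(pix, lab, fy, fx, size, frac):
    C, H, W = pix.shape
    if H < size or W < size:
        ph, pw = max(0, size - H), max(0, size - W)
        pix = np.pad(pix, ((0, 0), (0, ph), (0, pw)), mode="reflect")
        lab = np.pad(lab, ((0, ph), (0, pw)))
        fy = np.pad(fy, ((0, ph), (0, pw)))
        fx = np.pad(fx, ((0, ph), (0, pw)))
        H, W = pix.shape[-2:]
    top = int(round(frac[0] * (H - size)))
    left = int(round(frac[1] * (W - size)))
    sl = np.s_[top : top + size, left : left + size]
    return pix[:, sl[0], sl[1]], lab[sl], fy[sl], fx[sl]


def augment(
    sample: tuple[LabeledImage, FlowTarget],
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, FlowTarget]:
    """Draw a random transform and apply it to one (image, flows) sample."""
    img, flows = sample
    return apply_transform(img.pixels, img.labels, flows, draw_transform(cfg, rng))


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    net: FlowStyleNet
    log: pd.DataFrame = field(repr=False)


def train_model(
    init: FlowStyleNet | str,
    images: list[LabeledImage],
    cfg: TrainConfig,
    augment_cfg: AugmentConfig | None = None,
    net_config: NetConfig | None = None,
    weights: np.ndarray | None = None,
    flows: list[FlowTarget] | None = None,
) -> TrainResult:
    """Train a network on labelled images with the given schedule.

    Parameters
    ----------
    init
        ``"scratch"`` (requires ``net_config``) or an existing network to
        fine-tune; fine-tuning copies the network, so the original is left
        untouched.
    images
        Training set (already filtered for the minimum ROI count).
    cfg, augment_cfg
        Schedule and augmentation; augmentation crop defaults to the
        smallest image dimension rounded down to the network's divisor.
    weights
        Optional per-image sampling weights (e.g. equal-cluster sampling
        for the generalist baseline).
    flows
        Optional precomputed flow targets, one per image.

    Returns
    -------
    TrainResult with the trained network and a per-epoch (epoch, lr, loss)
    log. Raises :class:`TrainingError` if the loss goes non-finite.
    """
    if not images:
        raise ValueError("training set is empty")
    if isinstance(init, str):
        if init != "scratch":
            raise ValueError("init must be 'scratch' or a network")
        if net_config is None:
            raise ValueError("training from scratch requires net_config")
        net = build_network(net_config)
    else:
        net = init.clone()

    rng = np.random.default_rng(cfg.seed)
    if flows is None:
        flows = [masks_to_flows(im.labels) for im in images]
    norm_pixels = [normalize_percentile(im.pixels) for im in images]

    if augment_cfg is None:
        min_side = min(min(im.spatial_shape) for im in images)
        crop = max(net.cfg.divisor, (min_side // net.cfg.divisor) * net.cfg.divisor)
        augment_cfg = AugmentConfig(crop=min(crop, 64))

    opt = nn.SGD(
        net.parameters(),
        momentum=cfg.momentum,
        weight_decay=cfg.weight_decay,
        max_grad_norm=cfg.max_grad_norm,
    )
    records = []
    for epoch in range(cfg.epochs):
        lr = lr_schedule(cfg, epoch)
        epoch_losses = []
        for batch in make_epoch(len(images), cfg, rng, weights=weights):
            xs, insides, fys, fxs = [], [], [], []
            for idx in batch:
                pix, lab, ft = apply_transform(
                    norm_pixels[idx],
                    images[idx].labels,
                    flows[idx],
                    draw_transform(augment_cfg, rng),
                )
                xs.append(pix if pix.ndim == 3 else pix[None])
                insides.append(ft.inside_prob)
                fys.append(ft.flow_y)
                fxs.append(ft.flow_x)
            x = np.stack(xs)
            target_flows = np.stack(
                [np.stack([fy, fx]) for fy, fx in zip(fys, fxs)]
            )
            target_inside = np.stack(insides)[:, None]

            opt.zero_grad()
            maps, _style = net.forward(x, train=True)
            flow_pred = ag.channel_slice(maps, 1, 3)
            logit_pred = ag.channel_slice(maps, 0, 1)
            loss = ag.add(
                ag.mul(
                    ag.mean_square(ag.sub(flow_pred, target_flows)),
                    cfg.flow_loss_weight,
                ),
                ag.mul(
                    ag.bce_with_logits(logit_pred, target_inside),
                    cfg.prob_loss_weight,
                ),
            )
            if not np.isfinite(loss.data):
                raise TrainingError(f"loss diverged at epoch {epoch}")
            loss.backward()
            opt.step(lr)
            epoch_losses.append(float(loss.data))
        records.append(
            {"epoch": epoch, "lr": lr, "loss": float(np.mean(epoch_losses))}
        )
    return TrainResult(net=net, log=pd.DataFrame(records))
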