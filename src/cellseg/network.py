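"""Residual U-net predicting flow fields, inside-cell probability and a style vector.

The network maps a 1- or 2-channel tile to three output maps — the logit
of the probability of being inside a cell, and the y/x flow components —
plus a fixed-length *style vector*: the global average pool of the deepest
(most downsampled) feature maps, L2-normalised. The style vector is both a
compact descriptor of the image (it routes images to models in the zoo)
and, when ``broadcast_style`` is on, a conditioning signal: one learned
linear projection per decoder level turns it into a per-channel bias added
to the upsampling-path features, letting a single network modulate its
segmentation style image by image. ``broadcast_style=False`` computes the
vector but does not inject it (the ablation switch).

Implemented on the package's own numpy autodiff (:mod:`cellseg.nn`); all
computation is float32 on the CPU.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import autograd as ag
from .dataio import LabeledImage

__all__ = [
    "NetConfig",
    "FlowStyleNet",
    "ShapeError",
    "build_network",
    "extract_style",
    "normalize_percentile",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_TAG",
]

CHECKPOINT_TAG = "cellseg-checkpoint-v1"


class ShapeError(ValueError):
    """Input spatial size incompatible with the downsampling depth."""


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    n_levels — downsampling depth (default 4; desk-scale experiments use
    2); base_channels — channels at the highest resolution, doubling per
    level (default 32; desk tests 8–16); style_dim — length of the style
    vector, which must equal the deepest level's channel count and is
    derived when left as None (default configuration gives 256);
    broadcast_style — inject the style vector into the decoder;
    in_channels — 1 (cytoplasm) or 2 (cytoplasm + nucleus); seed — makes
    parameter initialisation deterministic.
    """

    n_levels: int = 4
    base_channels: int = 32
    style_dim: int | None = None
    broadcast_style: bool = True
    in_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 1 or self.base_channels < 1:
            raise ValueError("n_levels and base_channels must be positive")
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")
        deepest = self.base_channels * 2 ** (self.n_levels - 1)
        if self.style_dim is None:
            object.__setattr__(self, "style_dim", deepest)
        elif self.style_dim != deepest:
            raise ValueError(
                f"style_dim ({self.style_dim}) must equal the deepest channel "
                f"count ({deepest})"
            )

    @property
    def level_channels(self) -> list[int]:
        return [self.base_channels * 2**l for l in range(self.n_levels)]

    @property
    def divisor(self) -> int:
        return 2**self.n_levels


class FlowStyleNet(nn.layers.Module):
    """The residual U-net; see the module docstring for the contract."""

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.level_channels
        c_in = cfg.in_channels
        self.down = []
        for c in ch:
            self.down.append(nn.ResBlock(c_in, c, rng))
            c_in = c
        self.up_convs = [
            nn.Conv2d(ch[l + 1], ch[l], 3, rng) for l in range(cfg.n_levels - 1)
        ]
        self.skip_convs = [
            nn.Conv2d(ch[l], ch[l], 1, rng) for l in range(cfg.n_levels - 1)
        ]
        self.style_proj = [
            nn.Linear(cfg.style_dim, ch[l], rng) for l in range(cfg.n_levels - 1)
        ]
        self.dec_blocks = [
            nn.ResBlock(ch[l], ch[l], rng) for l in range(cfg.n_levels - 1)
        ]
        self.head = nn.Conv2d(ch[0], 3, 1, rng)

    # -- core passes ------------------------------------------------------

    def forward(self, x, train: bool = False) -> tuple[ag.Tensor, ag.Tensor]:
        """Run a batch of tiles.

        Parameters
        ----------
        x
            ``(N, in_channels, H, W)`` array or Tensor, H and W divisible
            by ``2**n_levels`` (callers pad).
        train
            Batch-norm mode and gradient tracking.

        Returns
        -------
        (maps, style) — ``maps`` is ``(N, 3, H, W)`` ordered (inside
        logit, flow_y, flow_x); ``style`` is the ``(N, style_dim)``
        L2-normalised style vector.
        """
        if not isinstance(x, ag.Tensor):
            x = ag.Tensor(np.asarray(x, dtype=np.float32))
        if np.isnan(x.data).any():
            raise FloatingPointError("NaN in network input")
        N, C, H, W = x.shape
        if C != self.cfg.in_channels:
            raise ShapeError(f"expected {self.cfg.in_channels} channels, got {C}")
        if H % self.cfg.divisor or W % self.cfg.divisor:
            raise ShapeError(
                f"spatial size {(H, W)} not divisible by {self.cfg.divisor}"
            )
        feats = []
        h = x
        for l, blk in enumerate(self.down):
            h = blk(h, train)
            feats.append(h)
            if l < self.cfg.n_levels - 1:
                h = ag.maxpool2(h)
        style = ag.l2_normalize_rows(ag.global_avg_pool(feats[-1]))
        h = feats[-1]
        for l in range(self.cfg.n_levels - 2, -1, -1):
            h = ag.upsample2(h)
            h = self.up_convs[l](h)
            h = ag.add(h, self.skip_convs[l](feats[l]))
            if self.cfg.broadcast_style:
                h = ag.affine_channels(h, self.style_proj[l](style))
            h = self.dec_blocks[l](h, train)
        return self.head(h), style

    def predict(
        self,
        image: np.ndarray | LabeledImage,
        normalized: bool = False,
        tile_size: int = 224,
        tile_overlap: float = 0.1,
    ):
        """Evaluate one image; returns a dict of numpy maps.

        The image is percentile-normalised (unless ``normalized``) and
        reflect-padded to a multiple of the downsampling factor; outputs
        are cropped back. Images larger than ``tile_size`` on either axis
        are processed as overlapping tiles (10% overlap by default) whose
        output maps are averaged in the overlap regions; the style vector
        is then the re-normalised mean of the tile styles. Keys:
        ``inside_prob``, ``flow_y``, ``flow_x``, ``style``.
        """
        pix = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
        if pix.ndim == 2:
            pix = pix[None]
        pix = pix.astype(np.float32)
        if not normalized:
            pix = normalize_percentile(pix)
        if pix.shape[0] != self.cfg.in_channels:
            if pix.shape[0] == 1 and self.cfg.in_channels == 2:
                pix = np.concatenate([pix, np.zeros_like(pix)], axis=0)
            else:
                pix = pix[: self.cfg.in_channels]

        H, W = pix.shape[-2:]
        if max(H, W) > tile_size:
            maps, style = self._predict_tiled(pix, tile_size, tile_overlap)
        else:
            padded, _ = _pad_to_multiple(pix, self.cfg.divisor)
            out, style_t = self.forward(padded[None], train=False)
            maps = out.data[0, :, :H, :W]
            style = style_t.data[0].copy()
        return {
            "inside_prob": 1.0 / (1.0 + np.exp(-maps[0])),
            "flow_y": maps[1],
            "flow_x": maps[2],
            "style": style,
        }

    def _predict_tiled(
        self, pix: np.ndarray, tile_size: int, overlap: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Sliding-tile forward pass, averaging maps where tiles overlap."""
        H, W = pix.shape[-2:]
        step = max(self.cfg.divisor, int(round(tile_size * (1.0 - overlap))))
        tops = _tile_starts(H, tile_size, step)
        lefts = _tile_starts(W, tile_size, step)
        acc = np.zeros((3, H, W), dtype=np.float64)
        weight = np.zeros((H, W), dtype=np.float64)
        styles = []
        for t in tops:
            for l in lefts:
                tile = pix[:, t : t + tile_size, l : l + tile_size]
                th, tw = tile.shape[-2:]
                padded, _ = _pad_to_multiple(tile, self.cfg.divisor)
                out, style_t = self.forward(padded[None], train=False)
                acc[:, t : t + th, l : l + tw] += out.data[0, :, :th, :tw]
                weight[t : t + th, l : l + tw] += 1.0
                styles.append(style_t.data[0])
        maps = (acc / weight).astype(np.float32)
        mean_style = np.mean(styles, axis=0)
        norm = np.linalg.norm(mean_style) + 1e-8
        return maps, (mean_style / norm).astype(np.float32)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def clone(self) -> "FlowStyleNet":
        other = FlowStyleNet(self.cfg)
        other.load_state_arrays(
            {k: v.copy() for k, v in self.state_arrays().items()}
        )
        return other


def build_network(cfg: NetConfig) -> FlowStyleNet:
    """Deterministically initialise a network from its config."""
    return FlowStyleNet(cfg)


def extract_style(net: FlowStyleNet, img: np.ndarray | LabeledImage) -> np.ndarray:
    """L2-normalised style vector of one image (length ``style_dim``)."""
    return net.predict(img)["style"]


def normalize_percentile(
    pix: np.ndarray, low: float = 1.0, high: float = 99.0
) -> np.ndarray:
    """Per-channel rescale of the 1st–99th percentile range to [0, 1]."""
    pix = np.asarray(pix, dtype=np.float32)
    if pix.ndim == 2:
        pix = pix[None]
    out = np.empty_like(pix)
    for c in range(pix.shape[0]):
        lo, hi = np.percentile(pix[c], [low, high])
        out[c] = np.zeros_like(pix[c]) if hi <= lo else (pix[c] - lo) / (hi - lo)
    return out


def _tile_starts(extent: int, tile: int, step: int) -> list[int]:
    """Start offsets so tiles of ``tile`` px cover [0, extent) fully."""
    if extent <= tile:
        return [0]
    starts = list(range(0, extent - tile, step))
    starts.append(extent - tile)
    return starts


def _pad_to_multiple(pix: np.ndarray, m: int) -> tuple[np.ndarray, tuple[int, int]]:
    C, H, W = pix.shape
    Hp = int(np.ceil(H / m)) * m
    Wp = int(np.ceil(W / m)) * m
    if (Hp, Wp) == (H, W):
        return pix, (H, W)
    padded = np.pad(pix, ((0, 0), (0, Hp - H), (0, Wp - W)), mode="reflect")
    return padded, (H, W)


# ---------------------------------------------------------------------------
# checkpoints: single-file .npz archive with a JSON config and all arrays
# ---------------------------------------------------------------------------

def save_checkpoint(net: FlowStyleNet, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "format": CHECKPOINT_TAG,
        "config": dataclasses.asdict(net.cfg),
        "meta": meta or {},
    }
    arrays = {f"arr::{k}": v for k, v in net.state_arrays().items()}
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> FlowStyleNet:
    with np.load(Path(path)) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        if header.get("format") != CHECKPOINT_TAG:
            raise ValueError(f"not a {CHECKPOINT_TAG} file: {path}")
        cfg = NetConfig(**header["config"])
        net = FlowStyleNet(cfg)
        state = {k[len("arr::"):]: z[k] for k in z.files if k.startswith("arr::")}
    net.load_state_arrays(state)
    return net
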