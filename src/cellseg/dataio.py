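"""Reading, writing and preparing labelled microscopy images.

The unit of data throughout the package is a :class:`LabeledImage`: an
intensity image (one or two channels) together with a dense instance label
map in which 0 is background and each positive integer id is one ROI
(region of interest, i.e. one segmented cell).

Besides plain I/O, this module implements the dataset-preparation operators
used when adapting heterogeneous ground truth for training:

* :func:`remove_overlaps` — flatten overlapping ROI annotations: ROI with
  more than 75% of their pixels shared with other ROI are dropped, and
  remaining contested pixels go to the ROI with the closest centroid.
* :func:`split_quarters` — cut an image into four tiles to build very small
  training subsets.
* :func:`enhance_contrast` — local contrast normalisation by a wide
  Gaussian ((I - G*I) / (G*I)).
* :func:`mirror_image` — flip both axes (used for within-annotator
  re-annotation protocols).
* :func:`filter_min_rois` — drop images with fewer than five ROI, which are
  too sparse to train on.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import imageio.v3 as iio
import tifffile
from scipy import ndimage

__all__ = [
    "LabeledImage",
    "RoiOverlapPolicy",
    "FormatError",
    "RangeError",
    "read_label_map",
    "write_label_map",
    "read_image",
    "write_image",
    "remove_overlaps",
    "split_quarters",
    "enhance_contrast",
    "mirror_image",
    "filter_min_rois",
    "write_manifest",
    "read_manifest",
]

CHANNEL_ROLES = ("cytoplasm", "nucleus", "none")


class FormatError(ValueError):
    """Raised when a file's pixel format is not an integer label map."""


class RangeError(ValueError):
    """Raised when label ids exceed the representable range of the output."""


@dataclass
class LabeledImage:
    """An intensity image paired with a dense instance label map.

    Parameters
    ----------
    pixels
        ``(H, W)`` or ``(C, H, W)`` intensity array, any dynamic range.
    labels
        ``(H, W)`` non-negative integer map; 0 is background, each positive
        id is one ROI. Ids need not be contiguous.
    channel_roles
        One tag per channel from ``{"cytoplasm", "nucleus", "none"}``.
    pixel_size
        Optional physical pixel size in micrometres per pixel.
    source_id
        Free-form provenance string.
    meta
        Extra per-image metadata (e.g. synthetic-scene bookkeeping).
    """

    pixels: np.ndarray
    labels: np.ndarray
    channel_roles: tuple[str, ...] = ("cytoplasm",)
    pixel_size: float | None = None
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D instance map")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("labels must have an integer dtype")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be (H, W) or (C, H, W)")
        if self.spatial_shape != self.labels.shape:
            raise ValueError(
                f"pixels spatial shape {self.spatial_shape} != labels shape "
                f"{self.labels.shape}"
            )
        roles = tuple(self.channel_roles)
        for r in roles:
            if r not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {r!r}")
        self.channel_roles = roles

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.pixels.shape[-2:]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[0]

    @property
    def roi_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_rois(self) -> int:
        return int(self.roi_ids.size)

    def with_labels(self, labels: np.ndarray) -> "LabeledImage":
        """Copy of this record with a replacement label map."""
        return dataclasses.replace(self, labels=np.asarray(labels))


@dataclass
class RoiOverlapPolicy:
    """How overlapping ROI annotations are flattened.

    ``removal_fraction`` — an ROI is removed outright when the fraction of
    its pixels shared with at least one other ROI exceeds this value
    (strictly greater). Remaining contested pixels are reassigned to the
    ROI with the closest centroid; ties break toward the lower ROI index.
    """

    removal_fraction: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.removal_fraction <= 1.0:
            raise ValueError("removal_fraction must lie in (0, 1]")


# ---------------------------------------------------------------------------
# plain file I/O
# ---------------------------------------------------------------------------

def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in (".tif", ".tiff")


def read_label_map(path: str | Path) -> np.ndarray:
    """Read an instance label map from an integer-valued PNG or TIFF.

    Raises :class:`FormatError` if the stored pixel type is not integral.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    arr = tifffile.imread(path) if _is_tiff(path) else iio.imread(path)
    arr = np.asarray(arr)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(
            f"label map {path} has non-integer dtype {arr.dtype}"
        )
    if arr.ndim != 2:
        raise FormatError(f"label map {path} is not single-channel 2D")
    return arr.astype(np.int32)


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Write an instance map as 16-bit single-channel TIFF/PNG (lossless)."""
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise FormatError("labels must have an integer dtype")
    if labels.min(initial=0) < 0:
        raise RangeError("labels must be non-negative")
    if labels.max(initial=0) > 65535:
        raise RangeError(
            f"max label id {labels.max()} exceeds 16-bit range (65535)"
        )
    out = labels.astype(np.uint16)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_tiff(path):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def read_image(path: str | Path) -> np.ndarray:
    """Read an intensity image; channel-last files become channel-first."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    arr = np.asarray(tifffile.imread(path) if _is_tiff(path) else iio.imread(path))
    if arr.ndim == 3 and arr.shape[-1] <= 4 and arr.shape[0] > 4:
        arr = np.moveaxis(arr, -1, 0)
    return arr


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pixels = np.asarray(pixels)
    if _is_tiff(path):
        kw = {"photometric": "minisblack"} if pixels.ndim == 3 else {}
        tifffile.imwrite(path, pixels, **kw)
    else:
        iio.imwrite(path, pixels)


# ---------------------------------------------------------------------------
# dataset preparation operators
# ---------------------------------------------------------------------------

def remove_overlaps(
    roi_sets: Sequence[np.ndarray],
    policy: RoiOverlapPolicy | None = None,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Flatten a list of possibly-overlapping ROI pixel sets into a map.

    Parameters
    ----------
    roi_sets
        One ``(n_i, 2)`` array of ``(row, col)`` coordinates per ROI. The
        output id of the i-th ROI is ``i + 1``.
    policy
        Removal/reassignment policy; defaults to the 75% rule.
    shape
        Canvas shape; inferred from the coordinates when omitted.

    Notes
    -----
    Overlap fractions are evaluated on the *original* sets, so the removal
    decision is independent of the subsequent reassignment: an ROI is
    dropped when more than ``removal_fraction`` of its pixels are shared
    with at least one other ROI. Surviving contested pixels then go to the
    surviving ROI whose centroid (mean of its original coordinates) is
    nearest; ties break toward the lower ROI index.
    """
    policy = policy or RoiOverlapPolicy()
    sets = [np.atleast_2d(np.asarray(s, dtype=np.int64)) for s in roi_sets]
    if not sets:
        return np.zeros(shape or (1, 1), dtype=np.int32)
    for i, s in enumerate(sets):
        if s.size == 0:
            raise ValueError(f"ROI {i} is empty")
    if shape is None:
        allpix = np.concatenate(sets, axis=0)
        shape = (int(allpix[:, 0].max()) + 1, int(allpix[:, 1].max()) + 1)

    count = np.zeros(shape, dtype=np.int32)
    for s in sets:
        count[s[:, 0], s[:, 1]] += 1

    # removal on the original sets
    keep: list[int] = []
    for i, s in enumerate(sets):
        frac = float(np.mean(count[s[:, 0], s[:, 1]] > 1))
        if frac <= policy.removal_fraction:
            keep.append(i)

    centroids = {i: sets[i].mean(axis=0) for i in keep}

    out = np.zeros(shape, dtype=np.int32)
    claims = np.zeros(shape, dtype=np.int32)
    for i in keep:
        s = sets[i]
        claims[s[:, 0], s[:, 1]] += 1
        out[s[:, 0], s[:, 1]] = i + 1  # provisional; contested fixed below
    contested = claims > 1
    if contested.any():
        for r, c in np.argwhere(contested):
            cands = [i for i in keep if _contains(sets[i], r, c)]
            d = [np.hypot(*(centroids[i] - (r, c))) for i in cands]
            out[r, c] = cands[int(np.argmin(d))] + 1  # argmin ties -> lower id
    return out


def _contains(coords: np.ndarray, r: int, c: int) -> bool:
    return bool(np.any((coords[:, 0] == r) & (coords[:, 1] == c)))


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Re-index positive ids to consecutive 1..K preserving order."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def split_quarters(img: LabeledImage) -> list[LabeledImage]:
    """Cut an image into four tiles by halving each axis.

    The first tile along each axis gets ``floor(H/2)`` rows; odd remainders
    attach to the last tile. ROI cut by a tile border keep only their
    in-tile pixels, and each tile's ids are re-indexed to consecutive
    integers.
    """
    H, W = img.spatial_shape
    if H < 2 or W < 2:
        raise ValueError("image too small to quarter")
    hs, ws = H // 2, W // 2
    tiles = []
    for qi, (r0, r1) in enumerate([(0, hs), (hs, H)]):
        for qj, (c0, c1) in enumerate([(0, ws), (ws, W)]):
            pix = img.pixels[..., r0:r1, c0:c1]
            lab = relabel_consecutive(img.labels[r0:r1, c0:c1])
            tiles.append(
                dataclasses.replace(
                    img,
                    pixels=pix.copy(),
                    labels=lab,
                    source_id=f"{img.source_id}/q{qi}{qj}",
                )
            )
    return tiles


def enhance_contrast(img: np.ndarray, kernel_width: float = 30.0) -> np.ndarray:
    """Local contrast normalisation: ``(I - G*I) / (G*I)``.

    ``G`` is a Gaussian smoother with sigma ``kernel_width`` pixels
    (default 30). The denominator is floored at ``1e-6 * max(I)`` so flat
    or dark images do not blow up; an all-zero image returns all zeros.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        return np.stack([enhance_contrast(c, kernel_width) for c in img])
    mx = float(np.abs(img).max(initial=0.0))
    if mx == 0.0:
        return np.zeros_like(img)
    smooth = ndimage.gaussian_filter(img, sigma=kernel_width)
    denom = np.maximum(smooth, 1e-6 * mx)
    return (img - smooth) / denom


def mirror_image(img: LabeledImage) -> LabeledImage:
    """Flip pixels and labels along both spatial axes (an involution)."""
    return dataclasses.replace(
        img,
        pixels=img.pixels[..., ::-1, ::-1].copy(),
        labels=img.labels[::-1, ::-1].copy(),
    )


def filter_min_rois(
    images: Sequence[LabeledImage], min_rois: int = 5
) -> list[LabeledImage]:
    """Keep only images with at least ``min_rois`` ROI (order preserved).

    Images with fewer than five ROI carry too little signal to train on
    and are excluded by default.
    """
    return [im for im in images if im.n_rois >= min_rois]


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(
    records: Sequence[tuple[str, str, Sequence[str]]], path: str | Path
) -> None:
    """Write a dataset manifest: (image path, label path, channel_roles)."""
    entries = [
        {"image": str(i), "labels": str(l), "channel_roles": list(r)}
        for i, l, r in records
    ]
    Path(path).write_text(json.dumps(entries, indent=2))


def read_manifest(path: str | Path) -> list[LabeledImage]:
    """Load every (image, labels) pair listed in a manifest JSON."""
    base = Path(path).parent
    out = []
    for e in json.loads(Path(path).read_text()):
        ipath, lpath = base / e["image"], base / e["labels"]
        out.append(
            LabeledImage(
                pixels=read_image(ipath),
                labels=read_label_map(lpath),
                channel_roles=tuple(e.get("channel_roles", ["cytoplasm"])),
                source_id=str(e["image"]),
            )
        )
    return out
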