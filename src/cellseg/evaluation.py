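"""Segmentation quality metrics: IoU matching and average precision.

The headline metric is the dataset-matching form of average precision used
in the Data Science Bowl family of benchmarks. Predicted masks are matched
one-to-one to ground-truth masks by IoU; matches with IoU at or above a
threshold are true positives (TP), unmatched predictions are false
positives (FP) and unmatched ground-truth ROI are false negatives (FN):

    AP = TP / (TP + FP + FN)

computed per image and averaged (unweighted) over a test set. Matching is
an optimal one-to-one assignment maximising total matched IoU (a greedy
mode is available for comparison; on uncontested instances the two agree).

Note this is *not* the COCO-style AP: no per-ROI confidence scores enter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .dataio import LabeledImage, mirror_image, split_quarters

__all__ = [
    "MatchResult",
    "ApReport",
    "DEFAULT_THRESHOLDS",
    "iou_matrix",
    "match_masks",
    "average_precision",
    "dataset_average_precision",
    "ap_vs_training_size",
    "within_annotator_bound",
]

#: IoU thresholds 0.5, 0.55, ..., 0.9; headline reports use 0.5.
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.5, 0.91, 0.05), 2))


@dataclass
class MatchResult:
    """One-to-one mask matching at a single IoU threshold."""

    pairs: list[tuple[int, int, float]]  # (predicted id, truth id, IoU)
    tp: int
    fp: int
    fn: int

    @property
    def ap(self) -> float:
        denom = self.tp + self.fp + self.fn
        return 1.0 if denom == 0 else self.tp / denom


@dataclass
class ApReport:
    """Average precision per IoU threshold, per image and dataset-mean."""

    thresholds: tuple[float, ...]
    per_image_ap: np.ndarray  # (n_images, n_thresholds)
    mean_ap: np.ndarray = field(init=False)  # (n_thresholds,)

    def __post_init__(self) -> None:
        self.per_image_ap = np.atleast_2d(np.asarray(self.per_image_ap, float))
        self.mean_ap = self.per_image_ap.mean(axis=0)

    def at(self, threshold: float) -> float:
        idx = int(np.argmin(np.abs(np.asarray(self.thresholds) - threshold)))
        return float(self.mean_ap[idx])


def iou_matrix(
    predicted: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise IoU between every predicted and every truth ROI.

    Returns ``(iou, pred_ids, truth_ids)`` where ``iou[i, j]`` is the
    intersection-over-union of predicted ROI ``pred_ids[i]`` with truth ROI
    ``truth_ids[j]``. Computed from the sparse joint histogram of the two
    maps, so only overlapping pairs cost anything.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("instance maps must share a canvas")
    pred_ids = np.unique(predicted)
    pred_ids = pred_ids[pred_ids > 0]
    truth_ids = np.unique(truth)
    truth_ids = truth_ids[truth_ids > 0]
    iou = np.zeros((pred_ids.size, truth_ids.size))
    if iou.size == 0:
        return iou, pred_ids, truth_ids

    p_index = {int(p): i for i, p in enumerate(pred_ids)}
    t_index = {int(t): j for j, t in enumerate(truth_ids)}
    p_area = {int(p): int(np.sum(predicted == p)) for p in pred_ids}
    t_area = {int(t): int(np.sum(truth == t)) for t in truth_ids}

    both = (predicted > 0) & (truth > 0)
    if both.any():
        pairs, counts = np.unique(
            np.stack([predicted[both], truth[both]]), axis=1, return_counts=True
        )
        for (p, t), inter in zip(pairs.T, counts):
            i, j = p_index[int(p)], t_index[int(t)]
            union = p_area[int(p)] + t_area[int(t)] - int(inter)
            iou[i, j] = inter / union
    return iou, pred_ids, truth_ids


def match_masks(
    ious: np.ndarray,
    threshold: float,
    pred_ids: Sequence[int] | None = None,
    truth_ids: Sequence[int] | None = None,
    greedy: bool = False,
) -> MatchResult:
    """One-to-one matching of predictions to truth at an IoU threshold.

    The default solves the optimal assignment maximising total matched IoU
    over pairs with IoU >= threshold. ``greedy=True`` instead repeatedly
    takes the highest remaining IoU pair; both agree whenever no truth ROI
    is contested by two predictions' best matches.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    ious = np.atleast_2d(np.asarray(ious, float))
    n_pred, n_truth = ious.shape
    pred_ids = list(pred_ids) if pred_ids is not None else list(range(1, n_pred + 1))
    truth_ids = list(truth_ids) if truth_ids is not None else list(range(1, n_truth + 1))

    eligible = np.where(ious >= threshold, ious, 0.0)
    pairs: list[tuple[int, int, float]] = []
    if n_pred and n_truth and eligible.any():
        if greedy:
            work = eligible.copy()
            while work.any():
                i, j = np.unravel_index(np.argmax(work), work.shape)
                pairs.append((pred_ids[i], truth_ids[j], float(ious[i, j])))
                work[i, :] = 0.0
                work[:, j] = 0.0
        else:
            rows, cols = linear_sum_assignment(eligible, maximize=True)
            for i, j in zip(rows, cols):
                if eligible[i, j] > 0.0:
                    pairs.append((pred_ids[i], truth_ids[j], float(ious[i, j])))
    tp = len(pairs)
    return MatchResult(pairs=pairs, tp=tp, fp=n_pred - tp, fn=n_truth - tp)


def average_precision(
    predicted: np.ndarray,
    truth: np.ndarray,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    greedy: bool = False,
) -> np.ndarray:
    """Per-threshold AP = TP/(TP+FP+FN) for a single image pair.

    An image with empty truth and empty prediction scores 1.0 (nothing to
    find, nothing hallucinated); empty truth with predictions scores 0.0.
    """
    thresholds = list(thresholds)
    if any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    ious, pred_ids, truth_ids = iou_matrix(predicted, truth)
    out = np.empty(len(thresholds))
    for k, th in enumerate(thresholds):
        m = match_masks(ious, th, pred_ids, truth_ids, greedy=greedy)
        out[k] = m.ap
    return out


def dataset_average_precision(
    predicted: Sequence[np.ndarray],
    truth: Sequence[np.ndarray],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> ApReport:
    """Unweighted mean over images of the per-image AP."""
    if len(predicted) != len(truth):
        raise ValueError("need one prediction per truth image")
    per_image = np.stack(
        [average_precision(p, t, thresholds) for p, t in zip(predicted, truth)]
    )
    return ApReport(thresholds=tuple(thresholds), per_image_ap=per_image)


def ap_vs_training_size(
    pool: Sequence[LabeledImage],
    sizes: Sequence[float],
    train_fn: Callable[[list[LabeledImage], int], Callable[[LabeledImage], np.ndarray]],
    test_set: Sequence[LabeledImage],
    replicates: int = 5,
    threshold: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Learning-curve table: AP at a threshold versus training-set size.

    ``sizes`` are in image units; fractional sizes 0.25 and 0.5 draw one or
    two quarter-tiles of a randomly chosen pool image. Each size is run
    ``replicates`` times with different random subsets; ``train_fn(images,
    seed)`` must return a callable mapping an image to a predicted instance
    map. Reports mean AP, its standard error over replicates, and the mean
    number of training ROI actually used.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for size in sizes:
        aps, nrois = [], []
        for rep in range(replicates):
            sub_seed = int(rng.integers(2**31 - 1))
            sub_rng = np.random.default_rng(sub_seed)
            if size < 1:
                src = pool[int(sub_rng.integers(len(pool)))]
                quarters = split_quarters(src)
                k = 1 if size <= 0.25 else 2
                picks = sub_rng.choice(4, size=k, replace=False)
                images = [quarters[i] for i in picks]
            else:
                n = int(round(size))
                if n > len(pool):
                    raise ValueError(f"subset size {n} exceeds pool of {len(pool)}")
                picks = sub_rng.choice(len(pool), size=n, replace=False)
                images = [pool[i] for i in picks]
            segment = train_fn(images, sub_seed)
            preds = [segment(im) for im in test_set]
            rep_ap = dataset_average_precision(
                preds, [im.labels for im in test_set], thresholds=[threshold]
            ).mean_ap[0]
            aps.append(rep_ap)
            nrois.append(sum(im.n_rois for im in images))
        aps = np.asarray(aps)
        rows.append(
            {
                "size": size,
                "n_train_roi": float(np.mean(nrois)),
                "mean_ap": float(aps.mean()),
                "sem": float(aps.std(ddof=1) / np.sqrt(len(aps))) if len(aps) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def within_annotator_bound(
    truth_a: np.ndarray,
    truth_b_mirrored: np.ndarray,
    threshold: float = 0.5,
    already_unmirrored: bool = False,
) -> float:
    """Agreement between two annotation passes of the same image.

    The second pass is assumed to have been drawn on a copy mirrored along
    both axes (to reduce memory effects) and is flipped back before
    comparison. Returns AP at the given threshold; this is an upper bound
    on what any model can score against either pass.
    """
    b = np.asarray(truth_b_mirrored)
    if not already_unmirrored:
        b = b[::-1, ::-1]
    if b.shape != np.asarray(truth_a).shape:
        raise ValueError("canvas mismatch after un-mirroring")
    return float(average_precision(b, truth_a, thresholds=[threshold])[0])
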