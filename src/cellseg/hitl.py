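"""Human-in-the-loop annotation and retraining, with a simulated annotator.

The loop mirrors interactive practice: segment the next image with the
current model; the annotator keeps the predictions that are good enough
and draws the ROI the model missed or got wrong; the model is then
retrained (short online schedule, re-initialised from the configured
starting checkpoint) on every image corrected so far, and the loop moves
to the next image.

Here the annotator is simulated against ground truth: a prediction is
*accepted* when it matches a truth ROI at IoU >= ``accept_iou`` (one-to-one
optimal matching); every unmatched truth ROI is copied verbatim into the
corrected map and counted as *manual* work; unmatched predictions are
deleted. This idealises a perfectly consistent human. The accounting per
round — predicted / accepted / manually added ROI — is the cost currency
of every comparison (the point of the loop is to minimise manual ROI).

The offline baseline annotates everything by hand (manual = all truth ROI)
and trains once with the long offline schedule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import LabeledImage, relabel_consecutive
from .evaluation import dataset_average_precision, iou_matrix, match_masks
from .network import FlowStyleNet
from .segment import segment_image
from .training import TrainConfig, train_model

__all__ = [
    "AnnotationRound",
    "HitlConfig",
    "simulate_correction",
    "run_hitl",
    "offline_baseline",
]


@dataclass
class AnnotationRound:
    """Accounting for one annotate-retrain iteration."""

    image_id: str
    n_predicted: int
    n_accepted: int
    n_manual: int
    checkpoint_id: str = ""

    def __post_init__(self) -> None:
        if self.n_accepted > self.n_predicted:
            raise ValueError("cannot accept more ROI than were predicted")


@dataclass
class HitlConfig:
    """Loop parameters.

    accept_iou — matching threshold above which a predicted ROI counts as
    good enough to keep (default 0.5, the headline AP threshold); rounds —
    number of images to iterate over; train_cfg — retraining schedule,
    online (100 epochs, no annealing) by default; warm_start — retrain
    from the previous round's weights instead of re-initialising from the
    original pretrained checkpoint each round (off by default: fixed
    re-initialisation keeps rounds comparable).
    """

    accept_iou: float = 0.5
    rounds: int = 5
    train_cfg: TrainConfig = field(default_factory=TrainConfig.online)
    warm_start: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.accept_iou < 1.0:
            raise ValueError("accept_iou must lie in (0, 1)")


def simulate_correction(
    predicted: np.ndarray,
    truth: np.ndarray,
    accept_iou: float = 0.5,
    image_id: str = "",
) -> tuple[np.ndarray, AnnotationRound]:
    """Correct a prediction against ground truth like an ideal annotator.

    Predictions matching a truth ROI at IoU >= ``accept_iou`` are kept
    verbatim; every other truth ROI is copied from the truth map (these
    are the manually drawn ones, and their strokes win any pixel conflict
    with an accepted prediction); unmatched predictions are deleted.
    Returns the corrected instance map and the round's accounting.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("prediction and truth must share a canvas")
    ious, pred_ids, truth_ids = iou_matrix(predicted, truth)
    n_predicted = int(pred_ids.size)
    match = match_masks(ious, accept_iou, pred_ids, truth_ids)
    accepted_pred = [p for p, _, _ in match.pairs]
    matched_truth = {t for _, t, _ in match.pairs}

    corrected = np.zeros_like(truth, dtype=np.int32)
    next_id = 1
    for p in accepted_pred:
        corrected[predicted == p] = next_id
        next_id += 1
    n_accepted = next_id - 1
    n_manual = 0
    for t in truth_ids:
        if int(t) in matched_truth:
            continue
        corrected[truth == t] = next_id  # the human's stroke wins conflicts
        next_id += 1
        n_manual += 1

    # an accepted prediction could in principle be wiped out entirely by
    # manual strokes; drop empty ids so the map stays a valid instance map
    survivors = np.unique(corrected)
    if len(survivors[survivors > 0]) != next_id - 1:
        present = set(int(s) for s in survivors if s > 0)
        lost_accepted = sum(1 for i in range(1, n_accepted + 1) if i not in present)
        n_accepted -= lost_accepted
        corrected = relabel_consecutive(corrected)
    round_log = AnnotationRound(
        image_id=image_id,
        n_predicted=n_predicted,
        n_accepted=n_accepted,
        n_manual=n_manual,
    )
    return corrected, round_log


def run_hitl(
    images: list[LabeledImage],
    test: list[LabeledImage],
    init: FlowStyleNet,
    cfg: HitlConfig,
) -> tuple[list[AnnotationRound], list[float], FlowStyleNet]:
    """Run the annotate-correct-retrain loop over an ordered image list.

    Each round segments the next image with the current model, corrects it
    against that image's ground truth, then retrains on all corrected
    images so far with the online schedule, re-initialised from ``init``
    (chained warm-starting is deliberately not the default: re-initialising
    from the same pretrained weights each round keeps rounds comparable).

    Returns the per-round accounting, the held-out AP@0.5 after each
    retrain, and the final model.
    """
    if not images:
        raise ValueError("need at least one training image")
    rounds = min(cfg.rounds, len(images))
    current = init
    corrected_so_far: list[LabeledImage] = []
    round_logs: list[AnnotationRound] = []
    test_ap: list[float] = []
    for r in range(rounds):
        im = images[r]
        predicted = segment_image(current, im)
        corrected, rlog = simulate_correction(
            predicted, im.labels, cfg.accept_iou, image_id=im.source_id or str(r)
        )
        rlog.checkpoint_id = f"round-{r}"
        round_logs.append(rlog)
        corrected_so_far.append(im.with_labels(corrected))
        train_cfg = dataclasses.replace(cfg.train_cfg, seed=cfg.train_cfg.seed + r)
        start = current if cfg.warm_start else init
        result = train_model(start, corrected_so_far, train_cfg)
        current = result.net
        preds = [segment_image(current, t) for t in test]
        ap = dataset_average_precision(
            preds, [t.labels for t in test], thresholds=[0.5]
        ).mean_ap[0]
        test_ap.append(float(ap))
    return round_logs, test_ap, current


def offline_baseline(
    images: list[LabeledImage],
    init: FlowStyleNet | str,
    cfg: TrainConfig | None = None,
    net_config=None,
) -> tuple[FlowStyleNet, int]:
    """Fully manual annotation + one offline training run.

    Every truth ROI is drawn by hand, so the manual count is simply the
    summed ROI count of the image list. Returns (model, total manual ROI).
    """
    cfg = cfg or TrainConfig.offline()
    total_manual = sum(im.n_rois for im in images)
    result = train_model(init, images, cfg, net_config=net_config)
    return result.net, total_manual
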