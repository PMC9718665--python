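"""Desk-scale experiment drivers.

Scaled-down, fully synthetic analogs of the method's headline experiments,
with every study condition (scene parameters, network size, schedule
lengths) fixed in one place. All experiments use a tiny network (2 levels,
8 base channels) on 64–96 px scenes so a full run fits in CPU minutes; the
schedule *structure* (warmup, plateau, optional annealing; online vs
offline) is the real one, with shortened epoch counts.

Experiments:

* :func:`flow_roundtrip_iou` — masks_to_flows -> follow_flows consistency
  on random convex-cell scenes.
* :func:`finetune_vs_scratch` — transfer: fine-tune a model pretrained on
  domain A using a couple of domain-B images, versus training from scratch
  at the same ROI budget.
* :func:`hitl_comparison` — the human-in-the-loop loop (simulated
  annotator) against a fully-manual offline baseline: manual-ROI totals,
  per-round counts, held-out AP.
* :func:`ensemble_vs_generalist` — style clustering + per-cluster
  specialists versus one generalist with equal-cluster sampling, on the
  two-style conflict benchmark; optionally with style broadcasting ablated
  throughout.
* :func:`routing_accuracy` — suggestion-mode accuracy on held-out images
  of the planted two-class benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import LabeledImage
from .evaluation import dataset_average_precision, iou_matrix, match_masks
from .flow import follow_flows, masks_to_flows
from .hitl import HitlConfig, offline_baseline, run_hitl
from .network import FlowStyleNet, NetConfig, build_network, extract_style
from .segment import segment_image
from .synthetic import (
    AnnotationStyle,
    SceneConfig,
    apply_style,
    generate_scene,
    make_two_style_benchmark,
)
from .training import AugmentConfig, TrainConfig, train_model
from .zoo import ModelZoo, cluster_styles, segment_with_ensemble, train_generalist

__all__ = [
    "DOMAIN_KW",
    "domain_scene",
    "desk_net_config",
    "pretrain_domain_a",
    "pretrain_no_orphan_annotator",
    "flow_roundtrip_iou",
    "finetune_vs_scratch",
    "hitl_comparison",
    "ensemble_vs_generalist",
    "routing_accuracy",
]

#: the two single-channel appearance domains of the transfer experiments:
#: a sparse image type with larger granular cells, and a denser one with
#: smaller flat-textured cells
DOMAIN_KW = {
    "A": dict(n_cells=6, diameter_mean=14.0, texture="granular"),
    "B": dict(n_cells=10, diameter_mean=11.0, texture="flat"),
}

#: training-time augmentation crop (px); all desk experiments share it
DESK_CROP = 48


def desk_net_config(in_channels: int = 1, seed: int = 7, broadcast_style: bool = True) -> NetConfig:
    """The desk-scale architecture: 2 levels, 8 base channels."""
    return NetConfig(
        n_levels=2, base_channels=8, in_channels=in_channels,
        broadcast_style=broadcast_style, seed=seed,
    )


def domain_scene(seed: int, domain: str, canvas=(64, 64)) -> LabeledImage:
    return generate_scene(
        SceneConfig(canvas=canvas, diameter_sd=1.2, noise_sd=0.04, seed=seed,
                    **DOMAIN_KW[domain])
    )


def _aug() -> AugmentConfig:
    return AugmentConfig(crop=DESK_CROP)


# ---------------------------------------------------------------------------
# flow round trip
# ---------------------------------------------------------------------------

def flow_roundtrip_iou(n_scenes: int = 50, seed: int = 0) -> float:
    """Mean matched per-ROI IoU of the flow round trip on convex cells.

    Unmatched truth ROI count as IoU 0, so the statistic is penalised for
    lost cells, not only for boundary errors.
    """
    rng = np.random.default_rng(seed)
    vals: list[float] = []
    for _ in range(n_scenes):
        scene = generate_scene(
            SceneConfig(
                canvas=(80, 80), n_cells=8, diameter_mean=12.0,
                diameter_sd=1.5, shape="ellipse", seed=int(rng.integers(2**31 - 1)),
            )
        )
        rec = follow_flows(masks_to_flows(scene.labels))
        ious, pi, ti = iou_matrix(rec, scene.labels)
        m = match_masks(ious, 0.5, pi, ti)
        vals.extend(iou for _, _, iou in m.pairs)
        vals.extend([0.0] * m.fn)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# pretraining fixtures
# ---------------------------------------------------------------------------

def pretrain_domain_a(seed: int = 0, n_images: int = 8, epochs: int = 100) -> FlowStyleNet:
    """Single-channel model trained on domain-A scenes (the 'pretrained'
    starting point of the transfer experiments)."""
    images = [domain_scene(seed * 1000 + s, "A") for s in range(n_images)]
    cfg = TrainConfig.online(epochs=epochs, seed=seed)
    return train_model(
        "scratch", images, cfg, augment_cfg=_aug(),
        net_config=desk_net_config(in_channels=1),
    ).net


def pretrain_no_orphan_annotator(seed: int = 0, n_images: int = 8, epochs: int = 100) -> FlowStyleNet:
    """Two-channel model whose training annotator never labelled orphan
    nuclei — the starting point of the HITL experiment, which then has to
    learn a style that does label them."""
    no_orphans = AnnotationStyle(label_orphan_nuclei=False)
    images = []
    for s in range(n_images):
        truth = generate_scene(
            SceneConfig(
                canvas=(64, 64), n_cells=8, diameter_mean=12.0, diameter_sd=1.2,
                texture="granular", nucleus_channel=True,
                nuclei_without_cyto_frac=0.25, noise_sd=0.04,
                seed=seed * 1000 + s,
            )
        )
        images.append(apply_style(truth, no_orphans))
    cfg = TrainConfig.online(epochs=epochs, seed=seed)
    return train_model(
        "scratch", images, cfg, augment_cfg=_aug(),
        net_config=desk_net_config(in_channels=2),
    ).net


# ---------------------------------------------------------------------------
# fine-tuning versus scratch
# ---------------------------------------------------------------------------

@dataclass
class TransferResult:
    finetuned_ap: list[float]
    scratch_ap: list[float]

    @property
    def margin(self) -> float:
        return float(np.mean(self.finetuned_ap) - np.mean(self.scratch_ap))


def finetune_vs_scratch(
    pretrained: FlowStyleNet,
    n_seeds: int = 5,
    n_images: int = 2,
    epochs: int = 60,
    seed: int = 0,
) -> TransferResult:
    """Fine-tune on a few domain-B images vs scratch at equal ROI budget.

    Both arms see exactly the same images and the same schedule; only the
    initialisation differs. AP@0.5 is measured on 4 held-out domain-B
    scenes shared across seeds.
    """
    test = [
        domain_scene((900 + s + 7919 * seed) % (2**31 - 1), "B") for s in range(4)
    ]
    truth = [im.labels for im in test]

    def ap_of(net):
        preds = [segment_image(net, im) for im in test]
        return float(dataset_average_precision(preds, truth, [0.5]).mean_ap[0])

    result = TransferResult([], [])
    for s in range(n_seeds):
        rng = np.random.default_rng(seed * 100 + s)
        images = [
            domain_scene(int(rng.integers(2**31 - 1)), "B")
            for _ in range(n_images)
        ]
        cfg = TrainConfig.online(epochs=epochs, seed=s)
        ft = train_model(pretrained, images, cfg, augment_cfg=_aug()).net
        sc = train_model(
            "scratch", images, cfg, augment_cfg=_aug(),
            net_config=desk_net_config(in_channels=1),
        ).net
        result.finetuned_ap.append(ap_of(ft))
        result.scratch_ap.append(ap_of(sc))
    return result


# ---------------------------------------------------------------------------
# human-in-the-loop versus offline
# ---------------------------------------------------------------------------

def _hitl_scene(seed: int) -> LabeledImage:
    """One image of the HITL target domain.

    The domain is deliberately *varied* — texture, object size and noise
    level differ image to image — so that absorbing it takes several
    annotation rounds rather than one; a homogeneous domain is mastered
    after the first corrected image and the per-round manual counts
    collapse to zero immediately, leaving no adaptation dynamics to
    measure.
    """
    r = np.random.default_rng(seed)
    return generate_scene(
        SceneConfig(
            canvas=(96, 96), n_cells=20,
            diameter_mean=float(r.uniform(10.0, 13.0)), diameter_sd=1.5,
            texture=str(r.choice(["flat", "granular", "membrane"])),
            nucleus_channel=True, nuclei_without_cyto_frac=0.3,
            noise_sd=float(r.uniform(0.05, 0.10)),
            seed=int(r.integers(2**31 - 1)),
        )
    )


@dataclass
class HitlResult:
    manual_per_round: np.ndarray  # (n_seeds, rounds)
    online_ap: list[float]  # final-round held-out AP per seed
    offline_ap: list[float]
    offline_manual: list[int]  # per-seed total truth ROI (full annotation)

    @property
    def online_manual_totals(self) -> np.ndarray:
        return self.manual_per_round.sum(axis=1)

    @property
    def round_means(self) -> np.ndarray:
        return self.manual_per_round.mean(axis=0)


def hitl_comparison(
    pretrained: FlowStyleNet,
    n_seeds: int = 5,
    rounds: int = 4,
    online_epochs: int = 60,
    offline_epochs: int = 100,
    n_test: int = 2,
    seed: int = 0,
) -> HitlResult:
    """Online/pretrained HITL versus offline/pretrained full annotation.

    The HITL images carry a style the pretrained model has not seen
    (orphan nuclei are labelled), so the first round requires real manual
    work which then declines as the retrained model absorbs the style.
    """
    manual = np.zeros((n_seeds, rounds), dtype=int)
    online_ap: list[float] = []
    offline_ap: list[float] = []
    offline_manual: list[int] = []
    for s in range(n_seeds):
        rng = np.random.default_rng((1000 + s + 104729 * seed) % (2**31 - 1))
        train_imgs = [_hitl_scene(int(rng.integers(2**31 - 1))) for _ in range(rounds)]
        test_imgs = [_hitl_scene(int(rng.integers(2**31 - 1))) for _ in range(n_test)]
        cfg = HitlConfig(
            rounds=rounds, train_cfg=TrainConfig.online(epochs=online_epochs, seed=s)
        )
        logs, aps, _final = run_hitl(train_imgs, test_imgs, pretrained, cfg)
        manual[s] = [l.n_manual for l in logs]
        online_ap.append(aps[-1])
        off_net, off_manual = offline_baseline(
            train_imgs, pretrained, TrainConfig.offline(epochs=offline_epochs, seed=s)
        )
        offline_manual.append(off_manual)
        preds = [segment_image(off_net, t) for t in test_imgs]
        offline_ap.append(
            float(
                dataset_average_precision(
                    preds, [t.labels for t in test_imgs], [0.5]
                ).mean_ap[0]
            )
        )
    return HitlResult(
        manual_per_round=manual,
        online_ap=online_ap,
        offline_ap=offline_ap,
        offline_manual=offline_manual,
    )


# ---------------------------------------------------------------------------
# ensemble versus generalist
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    ensemble_ap: list[float]
    generalist_ap: list[float]
    n_clusters: list[int]

    @property
    def gap(self) -> float:
        return float(np.mean(self.ensemble_ap) - np.mean(self.generalist_ap))


def _ensemble_cfg(epochs: int, seed: int) -> TrainConfig:
    # generalist-mode schedule structure at the desk scale; the tiny
    # network needs the 0.1 peak to train stably
    return TrainConfig.generalist(epochs=epochs, peak_lr=0.1, seed=seed)


def ensemble_vs_generalist(
    n_seeds: int = 5,
    epochs: int = 70,
    broadcast_style: bool = True,
    seed: int = 0,
) -> EnsembleResult:
    """Style-routed specialists versus one generalist on conflicting styles.

    Per seed: build the two-style benchmark, extract style vectors with a
    deterministically initialised network, cluster them (Leiden, resolution
    0.45), train one specialist per cluster and one generalist sampling
    clusters with equal probability, then score both on the styled test
    labels. ``broadcast_style=False`` ablates the style broadcast in every
    network involved.
    """
    result = EnsembleResult([], [], [])
    for s in range(n_seeds):
        bench = make_two_style_benchmark(
            seed=(2000 + s + 15485863 * seed) % (2**31 - 1)
        )
        net_cfg = desk_net_config(
            in_channels=2, seed=42, broadcast_style=broadcast_style
        )
        style_net = build_network(net_cfg)
        styles = np.stack([extract_style(style_net, im) for im in bench.train])
        cl = cluster_styles(styles, n_neighbors=5, resolution=0.45, seed=s)
        datasets = {
            cid: [bench.train[i] for i in range(len(bench.train)) if cl.labels[i] == cid]
            for cid in range(cl.n_clusters)
        }
        models = {
            cid: train_model(
                "scratch", imgs, _ensemble_cfg(epochs, s), augment_cfg=_aug(),
                net_config=net_cfg,
            ).net
            for cid, imgs in datasets.items()
        }
        zoo = ModelZoo(clustering=cl, models=models)
        generalist = train_generalist(
            datasets, _ensemble_cfg(epochs, s + 500), net_config=net_cfg
        )
        truth = [im.labels for im in bench.test]
        ens_maps, _log = segment_with_ensemble(zoo, bench.test, style_net)
        gen_maps = [segment_image(generalist, im) for im in bench.test]
        result.ensemble_ap.append(
            float(dataset_average_precision(ens_maps, truth, [0.5]).mean_ap[0])
        )
        result.generalist_ap.append(
            float(dataset_average_precision(gen_maps, truth, [0.5]).mean_ap[0])
        )
        result.n_clusters.append(cl.n_clusters)
    return result


# ---------------------------------------------------------------------------
# routing
# ---------------------------------------------------------------------------

def routing_accuracy(seed: int = 0, n_holdout_per_class: int = 25) -> float:
    """Suggestion-mode accuracy on held-out two-class images.

    Clusters the training styles, maps each cluster to its majority
    generating class, then routes fresh images; an image is correct when
    its assigned cluster's majority class matches its own.
    """
    bench = make_two_style_benchmark(seed=seed, n_train_per_class=8)
    style_net = build_network(desk_net_config(in_channels=2, seed=42))
    styles = np.stack([extract_style(style_net, im) for im in bench.train])
    classes = [im.meta["style_class"] for im in bench.train]
    cl = cluster_styles(styles, n_neighbors=5, resolution=0.45, seed=seed)
    majority = {}
    for cid in range(cl.n_clusters):
        members = [classes[i] for i in range(len(classes)) if cl.labels[i] == cid]
        majority[cid] = max(set(members), key=members.count)
    holdout = make_two_style_benchmark(
        seed=seed + 424243, n_train_per_class=0,
        n_test_per_class=n_holdout_per_class,
    )
    correct = 0
    for im in holdout.test:
        from .zoo import assign_cluster

        cid = assign_cluster(cl, extract_style(style_net, im))
        correct += majority[cid] == im.meta["style_class"]
    return correct / len(holdout.test)
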