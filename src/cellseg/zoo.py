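"""Style clustering, the model zoo, routing and the ensemble pipeline.

Images are summarised by their style vectors (:func:`network.extract_style`).
Style vectors of a reference corpus are clustered by building a K-nearest-
neighbour graph on Euclidean distances (default 100 neighbours, capped at
n-1 for small sets) and partitioning it with the Leiden algorithm at
resolution 0.45. One segmentation model is then trained per cluster — the
*zoo* — and new images are routed to a model by a 5-nearest-neighbour
majority vote among the clustered style vectors ("suggestion mode"). A
*generalist* baseline instead trains a single model on all clusters,
sampling clusters with equal probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .dataio import LabeledImage
from .flow import QcConfig
from .network import FlowStyleNet, extract_style, load_checkpoint, save_checkpoint
from .segment import segment_image
from .training import TrainConfig, TrainResult, train_model

__all__ = [
    "StyleClustering",
    "ModelZoo",
    "cluster_styles",
    "assign_cluster",
    "build_zoo",
    "train_generalist",
    "suggest_model",
    "segment_with_ensemble",
    "save_zoo",
    "load_zoo",
]


@dataclass
class StyleClustering:
    """A fitted style clustering: member vectors plus their cluster labels."""

    member_styles: np.ndarray  # (n, style_dim)
    labels: np.ndarray  # (n,) contiguous ids from 0
    n_neighbors: int
    resolution: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class ModelZoo:
    """One trained model per style cluster plus the K-NN router."""

    clustering: StyleClustering
    models: dict[int, FlowStyleNet] = field(default_factory=dict)
    router_k: int = 5

    def __post_init__(self) -> None:
        missing = set(range(self.clustering.n_clusters)) - set(self.models)
        if missing:
            raise ValueError(f"zoo is missing models for clusters {sorted(missing)}")


def cluster_styles(
    styles: np.ndarray,
    n_neighbors: int = 100,
    resolution: float = 0.45,
    seed: int = 0,
) -> StyleClustering:
    """Partition style vectors into segmentation-style groups.

    Builds an undirected K-NN graph on Euclidean distances and runs Leiden
    (RB-configuration objective) at the given resolution. ``n_neighbors``
    is capped at ``len(styles) - 1``. Cluster ids are re-indexed to be
    contiguous from 0 in order of first appearance; the partition is
    deterministic under ``seed``.
    """
    styles = np.asarray(styles, dtype=np.float64)
    n = styles.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 style vectors")
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(styles)
    _, idx = nn.kneighbors(styles)
    edges = {(min(i, int(j)), max(i, int(j))) for i in range(n) for j in idx[i, 1:]}
    graph = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    return StyleClustering(
        member_styles=styles.astype(np.float32),
        labels=labels,
        n_neighbors=k,
        resolution=resolution,
        seed=seed,
    )


def assign_cluster(
    clustering: StyleClustering, style: np.ndarray, k: int = 5
) -> int:
    """Majority vote among the k nearest clustered members (Euclidean).

    Vote ties break toward the lowest cluster id among the tied clusters.
    """
    if clustering.member_styles.size == 0:
        raise ValueError("empty clustering")
    style = np.asarray(style, dtype=np.float64).ravel()
    d = np.linalg.norm(clustering.member_styles - style, axis=1)
    k = min(k, d.size)
    nearest = np.argsort(d, kind="stable")[:k]
    votes = np.bincount(clustering.labels[nearest])
    return int(np.argmax(votes))  # argmax ties -> lowest cluster id


def build_zoo(
    clustering: StyleClustering,
    datasets: dict[int, list[LabeledImage]],
    cfg: TrainConfig,
    init: FlowStyleNet | str = "scratch",
    net_config=None,
) -> ModelZoo:
    """Train one model per style cluster on that cluster's images only."""
    models: dict[int, FlowStyleNet] = {}
    for cid in range(clustering.n_clusters):
        images = datasets.get(cid, [])
        if not images:
            raise ValueError(f"cluster {cid} has no training images")
        res: TrainResult = train_model(
            init, images, cfg, net_config=net_config
        )
        models[cid] = res.net
    return ModelZoo(clustering=clustering, models=models)


def train_generalist(
    datasets: dict[int, list[LabeledImage]],
    cfg: TrainConfig,
    init: FlowStyleNet | str = "scratch",
    net_config=None,
) -> FlowStyleNet:
    """Single model over all clusters, sampling clusters with equal probability.

    Images are pooled and weighted 1/(n_clusters * cluster size), so each
    cluster contributes equally per epoch regardless of its size.
    """
    pooled: list[LabeledImage] = []
    weights: list[float] = []
    n_clusters = len(datasets)
    for cid, images in sorted(datasets.items()):
        for im in images:
            pooled.append(im)
            weights.append(1.0 / (n_clusters * len(images)))
    res = train_model(
        init, pooled, cfg, net_config=net_config, weights=np.asarray(weights)
    )
    return res.net


def suggest_model(
    zoo: ModelZoo, image: LabeledImage | np.ndarray, style_net: FlowStyleNet
) -> tuple[int, FlowStyleNet]:
    """Route an image to the zoo model whose style cluster matches it."""
    style = extract_style(style_net, image)
    cid = assign_cluster(zoo.clustering, style, k=zoo.router_k)
    return cid, zoo.models[cid]


def segment_with_ensemble(
    zoo: ModelZoo,
    images: list[LabeledImage],
    style_net: FlowStyleNet,
    qc: QcConfig | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Route every image, segment it with its cluster's model, log routing."""
    maps: list[np.ndarray] = []
    log = []
    for i, im in enumerate(images):
        cid, model = suggest_model(zoo, im, style_net)
        maps.append(segment_image(model, im, qc=qc))
        log.append(
            {
                "index": i,
                "source_id": im.source_id,
                "cluster": cid,
                "style_class": im.meta.get("style_class"),
            }
        )
    return maps, pd.DataFrame(log)


def save_zoo(zoo: ModelZoo, dirpath: str | Path) -> None:
    """Persist a zoo as clustering JSON + one checkpoint per cluster."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    c = zoo.clustering
    (d / "clustering.json").write_text(
        json.dumps(
            {
                "member_styles": c.member_styles.tolist(),
                "labels": c.labels.tolist(),
                "n_neighbors": c.n_neighbors,
                "resolution": c.resolution,
                "seed": c.seed,
                "router_k": zoo.router_k,
            }
        )
    )
    for cid, net in zoo.models.items():
        save_checkpoint(net, d / f"cluster_{cid}.npz", meta={"cluster": cid})


def load_zoo(dirpath: str | Path) -> ModelZoo:
    d = Path(dirpath)
    spec = json.loads((d / "clustering.json").read_text())
    clustering = StyleClustering(
        member_styles=np.asarray(spec["member_styles"], dtype=np.float32),
        labels=np.asarray(spec["labels"], dtype=np.int64),
        n_neighbors=int(spec["n_neighbors"]),
        resolution=float(spec["resolution"]),
        seed=int(spec["seed"]),
    )
    models = {
        int(p.stem.split("_")[1]): load_checkpoint(p)
        for p in sorted(d.glob("cluster_*.npz"))
    }
    return ModelZoo(
        clustering=clustering, models=models, router_k=int(spec.get("router_k", 5))
    )
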