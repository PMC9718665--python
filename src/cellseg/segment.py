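"""End-to-end segmentation of one image with a trained network.

Chains the pieces defined elsewhere: percentile normalisation and the
network forward pass (:mod:`cellseg.network`), optional rescaling so the
image's object diameter matches the model's native diameter, flow
following and the flow-error quality-control filter (:mod:`cellseg.flow`).
"""

from __future__ import annotations

import numpy as np

from .dataio import LabeledImage
from .flow import (
    FlowTarget,
    QcConfig,
    follow_flows,
    remove_bad_flow_masks,
    resize_for_diameter,
    resize_labels_back,
)
from .network import FlowStyleNet

__all__ = ["segment_image"]


def segment_image(
    net: FlowStyleNet,
    image: LabeledImage | np.ndarray,
    qc: QcConfig | None = None,
    prob_threshold: float = 0.5,
    diameter: float | None = None,
    model_diameter: float | None = None,
) -> np.ndarray:
    """Segment one image; returns an instance label map.

    When both ``diameter`` (the dataset's typical object diameter) and
    ``model_diameter`` (the diameter the network was trained at) are
    given, the image is rescaled by their ratio before the forward pass
    and the resulting masks are mapped back to the original frame.
    """
    qc = qc or QcConfig()
    original_shape = None
    if diameter is not None and model_diameter is not None and diameter > 0:
        src = (
            image
            if isinstance(image, LabeledImage)
            else LabeledImage(
                pixels=np.asarray(image),
                labels=np.zeros(np.asarray(image).shape[-2:], dtype=np.int32),
            )
        )
        original_shape = src.spatial_shape
        image = resize_for_diameter(src, diameter, model_diameter)
    pred = net.predict(image)
    flows = FlowTarget(pred["flow_y"], pred["flow_x"], pred["inside_prob"])
    masks = follow_flows(
        flows, prob_threshold=prob_threshold, min_roi_size=qc.min_roi_size
    )
    masks = remove_bad_flow_masks(flows, masks, qc)
    if original_shape is not None:
        masks = resize_labels_back(masks, original_shape)
    return masks
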