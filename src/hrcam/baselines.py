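"""Baseline class activation maps: Zhou's GAP-CAM and Grad-CAM.

Both return the same :class:`~hrcam.maps.ActivationMap` container as
the high-resolution method, so evaluation is method-blind.

Zhou-CAM weights the final convolutional layer's feature maps by the
model's own GAP-head class weights.  Grad-CAM weights a chosen layer's
feature maps by the spatial mean of the gradient of the class *score*
(the pre-softmax logit) with respect to that layer, rectifies the
weighted sum, and upsamples.  Rectification belongs to Grad-CAM's
definition only; Zhou-CAM and HR-CAM keep signed values.
"""

from __future__ import annotations

import numpy as np

from ._nn import GlobalAvgPool
from .backbone import CNNClassifier, TapSpec, harvest_features
from .head import HeadWeights, compose_map
from .maps import ActivationMap, bilinear_upsample, min_max_normalize


def _require_gap_head(model: CNNClassifier) -> None:
    if not any(isinstance(n.layer, GlobalAvgPool) for n in model.network.nodes):
        raise ValueError("model lacks a global-average-pooling head")


def zhou_head(model: CNNClassifier) -> HeadWeights:
    """A k=1 head over the final tap, weights copied from the model's
    own dense layer (the classic GAP-CAM configuration)."""
    _require_gap_head(model)
    spec = model.tap_spec
    final = TapSpec([spec.layer_ids[-1]], [spec.channels[-1]],
                    [spec.spatial_sizes[-1]])
    fc = model.network.by_name["fc"].layer
    return HeadWeights(tap_spec=final, class_count=model.class_count,
                       W=fc.params["W"].copy(),
                       bias=fc.params["b"].copy(), trained=True)


def zhou_cam(model: CNNClassifier, image, class_id: int | None = None
             ) -> ActivationMap:
    """GAP-CAM from the final convolutional layer (min-max normalized)."""
    _require_gap_head(model)
    head = zhou_head(model)
    bundle = harvest_features(model, image, head.tap_spec)
    if class_id is None:
        class_id = int(model.predict([image])[0])
    amap = compose_map(bundle, head, class_id, model.input_size)
    amap.source_method = "zhou_cam"
    return min_max_normalize(amap)


def grad_cam(model: CNNClassifier, image, class_id: int | None = None,
             layer_id: str | None = None) -> ActivationMap:
    """Gradient-weighted CAM at ``layer_id`` (min-max normalized).

    Default layer is the last convolutional output of the penultimate
    resolution stage (the pre-final block).  Channel weights are the
    spatial means of d(logit_c)/d(feature map); the weighted sum is
    rectified before upsampling.
    """
    if layer_id is None:
        spec = model.tap_spec
        layer_id = (spec.layer_ids[-2] if spec.k >= 2 else spec.layer_ids[-1])
    if layer_id not in model.network.by_name:
        raise ValueError(f"unknown layer {layer_id!r}")
    x = model._as_batch([image])
    acts = model.network.forward(x)
    logits = acts[model.network.output_name]
    if class_id is None:
        class_id = int(logits[0].argmax())
    if not 0 <= class_id < model.class_count:
        raise ValueError(f"unknown class id {class_id}")
    g_out = np.zeros_like(logits)
    g_out[0, class_id] = 1.0
    model.network.zero_grad()
    gacts = model.network.backward(g_out)
    if layer_id not in gacts:
        raise ValueError(f"no gradient flows to layer {layer_id!r}")
    grads = gacts[layer_id][0]          # (m, h, w)
    fmaps = acts[layer_id][0]
    alpha = grads.mean(axis=(1, 2))     # spatial mean per channel
    cam = np.maximum(np.tensordot(alpha, fmaps, axes=(0, 0)), 0.0)
    if cam.shape != model.input_size:
        cam = bilinear_upsample(cam, model.input_size)
    amap = ActivationMap(values=cam, class_id=class_id, normalized=False,
                         source_method="grad_cam")
    return min_max_normalize(amap)


def gradcam_channel_weights(model: CNNClassifier, image, class_id: int,
                            layer_id: str) -> np.ndarray:
    """The per-channel Grad-CAM weights alpha (exposed for verification)."""
    x = model._as_batch([image])
    acts = model.network.forward(x)
    g_out = np.zeros_like(acts[model.network.output_name])
    g_out[0, class_id] = 1.0
    model.network.zero_grad()
    gacts = model.network.backward(g_out)
    return gacts[layer_id][0].mean(axis=(1, 2))
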