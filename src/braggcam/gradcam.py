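"""Gradient-weighted class activation mapping and guided backpropagation.

For a class score :math:`y^c` (the raw pre-softmax classifier score) and the
post-ReLU feature maps :math:`A^k` of a convolutional layer:

1. compute :math:`\\partial y^c / \\partial A^k`;
2. average-pool those gradients over width and height to get the neuron
   importance weights :math:`\\alpha_k^c`;
3. form :math:`L^c = \\mathrm{ReLU}(\\sum_k \\alpha_k^c A^k)`;
4. bilinearly upsample :math:`L^c` to the input size and min-max normalize to
   [0, 1] (an all-zero map stays all-zero);
5. blend the colormapped heat map with the input for presentation.

Guided backpropagation modifies every ReLU's backward rule to pass gradient
only where the forward input was positive *and* the incoming gradient is
positive; its elementwise product with the upsampled heat map is the guided
Grad-CAM visualization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from .frames import DetectorFrame
from .models import CNNModel

__all__ = [
    "GradCamResult",
    "GuidedGrads",
    "score_gradients",
    "neuron_importance",
    "gradcam",
    "guided_backprop",
    "guided_gradcam",
    "activation_histogram",
    "localization_score",
    "overlay_heatmap",
]

FrameLike = Union[DetectorFrame, np.ndarray]


@dataclass
class GradCamResult:
    layer: str
    class_index: int
    importance: np.ndarray  # alpha_k^c, shape (K,)
    raw_map: np.ndarray     # L^c before upsampling, shape (h, w), >= 0
    heatmap: np.ndarray     # upsampled + min-max normalized, input-sized, in [0, 1]
    logits: np.ndarray


@dataclass
class GuidedGrads:
    class_index: int
    grad: np.ndarray  # signed pixel-space gradient, input-sized


def _resolve_class(model: CNNModel, frame: FrameLike, class_index: Optional[int]):
    logits = model.forward(frame)
    if class_index is None:
        class_index = int(np.argmax(logits))
    if not (0 <= class_index < model.spec.n_classes):
        raise ValueError(f"class index {class_index} out of range")
    return class_index, logits


def score_gradients(
    model: CNNModel, frame: FrameLike, class_index: int, layer: str
) -> np.ndarray:
    """Gradient of the raw class score w.r.t. the layer's feature maps A^k."""
    if layer not in model.net.taps:
        raise KeyError(f"unknown layer {layer!r}")
    x = model.preprocess(frame)
    logits, _, caches = model.net.forward(x, want_caches=True)
    seed = np.zeros_like(logits)
    seed[0, class_index] = 1.0
    d, _ = model.net.backward(seed, caches, stop_layer=layer)
    return d[0]


def neuron_importance(grads: np.ndarray) -> np.ndarray:
    """alpha_k^c: spatial mean of the score gradients, one weight per map."""
    grads = np.asarray(grads)
    if grads.ndim != 3:
        raise ValueError("expected gradients shaped (K, h, w)")
    return grads.mean(axis=(1, 2))


def _upsample(raw: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize

    if raw.shape == tuple(shape):
        return raw.copy()
    return resize(raw, shape, order=1, mode="edge", anti_aliasing=False,
                  preserve_range=True)


def gradcam(
    model: CNNModel,
    frame: FrameLike,
    class_index: Optional[int] = None,
    layer: Optional[str] = None,
) -> GradCamResult:
    """Class-localization heat map for one frame.

    ``class_index`` defaults to the predicted class, ``layer`` to the last
    convolutional layer (last residual stage for resnet-style models).
    """
    layer = layer or model.spec.last_conv_layer
    class_index, logits = _resolve_class(model, frame, class_index)

    x = model.preprocess(frame)
    _, named, caches = model.net.forward(x, want_caches=True)
    acts = named[layer][0]  # (K, h, w)
    seed = np.zeros((1, model.spec.n_classes))
    seed[0, class_index] = 1.0
    dacts, _ = model.net.backward(seed, caches, stop_layer=layer)

    alpha = neuron_importance(dacts[0])
    raw = np.maximum(np.tensordot(alpha, acts, axes=1), 0.0)

    size = model.spec.input_size
    heat = _upsample(raw, (size, size))
    peak = heat.max()
    heatmap = heat / peak if peak > 0 else np.zeros_like(heat)
    return GradCamResult(layer, class_index, alpha, raw, heatmap, logits)


def guided_backprop(
    model: CNNModel, frame: FrameLike, class_index: Optional[int] = None
) -> GuidedGrads:
    """Guided-ReLU pixel-space gradient of the class score.

    Channel-replicated inputs collapse back to one map by averaging over the
    input channels.
    """
    class_index, _ = _resolve_class(model, frame, class_index)
    x = model.preprocess(frame)
    logits, _, caches = model.net.forward(x, want_caches=True)
    seed = np.zeros_like(logits)
    seed[0, class_index] = 1.0
    dx, _ = model.net.backward(seed, caches, guided=True)
    return GuidedGrads(class_index, dx[0].mean(axis=0))


def guided_gradcam(result: GradCamResult, guided: GuidedGrads) -> np.ndarray:
    """Elementwise product of the normalized heat map and the guided gradients."""
    if result.heatmap.shape != guided.grad.shape:
        raise ValueError(
            f"shape mismatch: heatmap {result.heatmap.shape} vs guided {guided.grad.shape}"
        )
    return result.heatmap * guided.grad


def activation_histogram(values: np.ndarray, n_bins: int = 50) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of activation (or heat-map) values; counts sum to the size."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = np.asarray(values).ravel()
    counts, edges = np.histogram(values, bins=n_bins)
    return edges, counts


def localization_score(heatmap: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of total heat-map mass falling inside the ground-truth mask."""
    heatmap = np.asarray(heatmap, float)
    mask = np.asarray(mask, bool)
    if heatmap.shape != mask.shape:
        raise ValueError("heatmap and mask shapes differ")
    total = heatmap.sum()
    if total <= 0:
        raise ValueError("all-zero heat map: localization undefined")
    return float(heatmap[mask].sum() / total)


def overlay_heatmap(frame: FrameLike, heatmap: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """RGB rendering: jet-colormapped heat map alpha-blended on the grayscale frame."""
    from matplotlib import cm

    pixels = np.asarray(frame.pixels if isinstance(frame, DetectorFrame) else frame, float)
    span = pixels.max() - pixels.min()
    gray = (pixels - pixels.min()) / (span + 1e-12)
    base = np.repeat(gray[:, :, None], 3, axis=2)
    color = cm.jet(np.clip(heatmap, 0, 1))[:, :, :3]
    return (1 - alpha) * base + alpha * color
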