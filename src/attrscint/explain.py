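"""Classifier interpretability: GradCAM and occlusion sensitivity.

Both produce a [0,1]-scaled saliency map aligned with the classifier input;
thresholding the map yields a binary overlay mask highlighting the regions
driving the decision (expected to sit on the cardiac area for uptake-driven
classifications).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as sk_resize

from ._nn import Conv2D, ReLU, Sequential, softmax
from .datatypes import LabelMask


@dataclass
class SaliencyMap:
    values: np.ndarray
    method: str
    target_class: int
    threshold: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("saliency values must be 2D")


def _as_net(model) -> Sequential:
    return model.net if hasattr(model, "net") else model


def _rescale01(values: np.ndarray) -> np.ndarray:
    vmax, vmin = values.max(), values.min()
    if vmax - vmin <= 0:
        return np.zeros_like(values)
    return (values - vmin) / (vmax - vmin)


def gradcam(model, img: np.ndarray, target_class: int, layer: int | None = None) -> SaliencyMap:
    """Gradient-weighted class activation map at the last convolutional stage.

    Channel weights are the spatially pooled gradients of the target-class
    logit; the rectified weighted activation sum is bilinearly upsampled to the
    input size and min-max rescaled to [0,1].
    """
    net = _as_net(model)
    if hasattr(model, "best_state") and model.best_state is not None:
        net.set_state(model.best_state)
    x = np.asarray(img, dtype=np.float64)[None, None]
    logits = net.forward(x, cache=True)
    if layer is None:
        spatial = [
            i for i, (lay, out) in enumerate(zip(net.layers, net.outputs))
            if isinstance(lay, (Conv2D, ReLU)) and out.ndim == 4
        ]
        if not spatial:
            raise ValueError("model has no spatial activations for GradCAM")
        layer = spatial[-1]
    acts = net.outputs[layer]
    if acts.ndim != 4:
        raise ValueError("chosen layer has no spatial activations")
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    _, grads = net.backward(dlogits, collect=True)
    g = grads[layer]
    weights = g[0].mean(axis=(1, 2))  # (C,)
    cam = np.maximum((weights[:, None, None] * acts[0]).sum(axis=0), 0.0)
    cam = sk_resize(cam, x.shape[2:], order=1, anti_aliasing=False)
    return SaliencyMap(_rescale01(cam), method="gradcam", target_class=target_class)


def occlusion_sensitivity(
    model, img: np.ndarray, target_class: int,
    patch_hw: tuple[int, int] = (16, 16), stride: int = 8,
) -> SaliencyMap:
    """Probability drop when a zero patch slides over the input.

    Each location's value is the mean drop of the target-class probability
    over the windows covering it; the map is rescaled to [0,1].
    """
    net = _as_net(model)
    if hasattr(model, "best_state") and model.best_state is not None:
        net.set_state(model.best_state)
    x = np.asarray(img, dtype=np.float64)
    h, w = x.shape
    ph, pw = patch_hw
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if ph >= h or pw >= w:
        raise ValueError("occlusion patch must be smaller than the image")

    def prob(arr):
        return softmax(net.forward(arr[None, None]))[0, target_class]

    base = prob(x)
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    rows = sorted({*range(0, h - ph + 1, stride), h - ph})
    cols = sorted({*range(0, w - pw + 1, stride), w - pw})
    for r in rows:
        for c in cols:
            occluded = x.copy()
            occluded[r : r + ph, c : c + pw] = 0.0
            drop = base - prob(occluded)
            acc[r : r + ph, c : c + pw] += drop
            cnt[r : r + ph, c : c + pw] += 1
    values = acc / np.maximum(cnt, 1)
    return SaliencyMap(
        _rescale01(values), method="occlusion", target_class=target_class
    )


def threshold_overlay(smap: SaliencyMap, threshold: float = 0.5) -> LabelMask:
    """Binary overlay: pixels with saliency >= threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    return LabelMask(
        smap.values >= threshold, structure="saliency", spacing_mm=(1.0, 1.0)
    )
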