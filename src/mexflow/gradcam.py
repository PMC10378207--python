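"""Grad-CAM visualization of the trained flow network.

The class-discriminative heatmap is computed at the post-MOFRW feature map
(the concatenated, reweighted three-branch features): channel weights are
the spatially averaged gradients of the chosen class logit with respect to
that map, the weighted channel sum is rectified, bilinearly upsampled to the
input resolution and min-max normalized to [0, 1]. A constant logit (zero
gradient everywhere) yields the all-zero heatmap.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from skimage.transform import resize

from .autodiff import Tensor
from .network import FlowNet
from .types import InputError

__all__ = ["grad_cam"]

_LAYERS = {"mofrw"}


def grad_cam(model: FlowNet, triplet: np.ndarray,
             target_layer: str = "mofrw",
             class_index: Optional[int] = None,
             method: str = "gradcam") -> np.ndarray:
    """Heatmap (input_size x input_size, values in [0, 1]) for one triplet.

    ``class_index`` defaults to the model's predicted class. ``method``
    selects the attribution rule: ``"gradcam"`` weights each channel by its
    spatially averaged gradient; ``"hires"`` keeps the element-wise
    gradient-activation product before summing over channels, which
    preserves the spatial structure of the gradient (with this model's
    global-average-pooled head the two coincide up to the constant
    per-channel gradient; the distinction matters for dense heads).
    """
    if target_layer not in _LAYERS:
        raise InputError(
            f"unknown target layer {target_layer!r}; available: {sorted(_LAYERS)}")
    if method not in {"gradcam", "hires"}:
        raise InputError(f"unknown attribution method {method!r}")
    x = np.asarray(triplet, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.shape[1] != 3:
        raise InputError("triplet must have 3 channels")
    model.eval()
    xt = Tensor(x)
    feat = model.features(xt)                        # (1, C, h, w)
    pooled = feat.mean(axis=(2, 3))
    logits = model.head(pooled)
    if class_index is None:
        class_index = int(np.argmax(logits.data[0]))
    if not (0 <= class_index < logits.shape[1]):
        raise InputError("class index out of range")
    onehot = np.zeros_like(logits.data)
    onehot[0, class_index] = 1.0
    logits.backward(onehot)
    grads = feat.grad[0]                             # (C, h, w)
    if method == "hires":
        cam = np.maximum((grads * feat.data[0]).sum(axis=0), 0.0)
    else:
        weights = grads.mean(axis=(1, 2))            # GAP of gradients
        cam = np.maximum(
            (weights[:, None, None] * feat.data[0]).sum(axis=0), 0.0)
    size = x.shape[-1]
    cam = resize(cam, (size, size), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    lo, hi = cam.min(), cam.max()
    if hi - lo == 0:
        return np.zeros((size, size))
    return (cam - lo) / (hi - lo)
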