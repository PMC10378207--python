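"""Class-imbalance-aware classification losses.

The headline loss is logit-adjusted softmax cross-entropy (LASCE): class
priors p_y estimated on the training split are turned into additive logit
corrections

    a_y = log(p_y^tau + eps),

and standard softmax cross-entropy is applied to the adjusted logits
``logits + a``. Because a_y is more negative for rare classes, the adjusted
decision boundary shifts toward the majority classes during training, which
forces the learned logits to compensate — at tau = 0 every a_y is log(1+eps)
and LASCE reduces exactly to ordinary cross-entropy. Plain cross-entropy,
focal loss and a logit-adjusted focal variant are provided for ablations.

All losses accept logits as numpy arrays or autodiff Tensors and return a
scalar Tensor (mean over the batch), so they can sit directly in the
training graph; use ``float(loss)`` for the value.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .autodiff import Tensor
from .types import InputError, PriorAdjustment

__all__ = ["class_priors", "correction_factors", "prior_adjustment",
           "ce_loss", "lasce_loss", "focal_loss", "la_focal_loss", "get_loss"]

ArrayLike = Union[np.ndarray, Tensor]


def class_priors(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Empirical class frequencies p_y = count(y) / n."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise InputError("cannot estimate priors from zero labels")
    if labels.min() < 0 or labels.max() >= n_classes:
        raise InputError("label outside [0, n_classes)")
    counts = np.bincount(labels.astype(np.int64), minlength=n_classes)
    return counts / counts.sum()


def correction_factors(p: np.ndarray, tau: float = 0.5,
                       eps: float = 1e-12) -> np.ndarray:
    """Logit corrections a_y = log(p_y^tau + eps), finite even for p_y = 0."""
    if tau < 0:
        raise InputError("tau must be >= 0")
    if eps <= 0:
        raise InputError("eps must be > 0")
    p = np.asarray(p, dtype=np.float64)
    return np.log(p ** tau + eps)


def prior_adjustment(labels: np.ndarray, n_classes: int, tau: float = 0.5,
                     eps: float = 1e-12) -> PriorAdjustment:
    p = class_priors(labels, n_classes)
    return PriorAdjustment(p=p, a=correction_factors(p, tau, eps),
                           tau=tau, eps=eps)


def _as_tensor(logits: ArrayLike) -> Tensor:
    if isinstance(logits, Tensor):
        if not np.all(np.isfinite(logits.data)):
            raise InputError("logits contain non-finite values")
        return logits
    arr = np.asarray(logits, dtype=np.float32)
    if not np.all(np.isfinite(arr)):
        raise InputError("logits contain non-finite values")
    return Tensor(arr)


def _check(logits: Tensor, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    if logits.ndim != 2 or labels.ndim != 1 or len(labels) != logits.shape[0]:
        raise InputError("logits must be (B, C) with one label per row")
    if labels.min() < 0 or labels.max() >= logits.shape[1]:
        raise InputError("label outside [0, n_classes)")
    return labels


def ce_loss(logits: ArrayLike, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy, computed in log-sum-exp stable form."""
    z = _as_tensor(logits)
    labels = _check(z, labels)
    return (z.logsumexp(axis=1) - z.gather(labels)).mean()


def lasce_loss(logits: ArrayLike, labels: np.ndarray,
               adj: PriorAdjustment) -> Tensor:
    """Logit-adjusted softmax cross-entropy on ``logits + a``."""
    z = _as_tensor(logits)
    labels = _check(z, labels)
    if len(adj.a) != z.shape[1]:
        raise InputError("adjustment length must equal number of classes")
    return ce_loss(z + adj.a.astype(z.data.dtype), labels)


def _focal_from_adjusted(z: Tensor, labels: np.ndarray, gamma: float) -> Tensor:
    log_q = z.gather(labels) - z.logsumexp(axis=1)   # log softmax at the label
    q = log_q.exp()
    mod = (1.0 - q).pow_const(gamma) if gamma != 0 else Tensor(
        np.ones_like(q.data))
    return (mod * (-log_q)).mean()


def focal_loss(logits: ArrayLike, labels: np.ndarray,
               gamma: float = 2.0) -> Tensor:
    """Focal loss: mean of -(1-q_y)^gamma log q_y with q = softmax(logits)."""
    if gamma < 0:
        raise InputError("gamma must be >= 0")
    z = _as_tensor(logits)
    labels = _check(z, labels)
    return _focal_from_adjusted(z, labels, gamma)


def la_focal_loss(logits: ArrayLike, labels: np.ndarray, adj: PriorAdjustment,
                  gamma: float = 2.0) -> Tensor:
    """Focal modulation applied to the prior-adjusted logits."""
    if gamma < 0:
        raise InputError("gamma must be >= 0")
    z = _as_tensor(logits)
    labels = _check(z, labels)
    if len(adj.a) != z.shape[1]:
        raise InputError("adjustment length must equal number of classes")
    return _focal_from_adjusted(z + adj.a.astype(z.data.dtype), labels, gamma)


def get_loss(name: str, adj: Optional[PriorAdjustment] = None,
             gamma: float = 2.0):
    """Return ``loss(logits, labels)`` for a config key in {ce, focal, lasce, la_focal}."""
    if name == "ce":
        return ce_loss
    if name == "focal":
        return lambda z, y: focal_loss(z, y, gamma)
    if name in {"lasce", "la_focal"}:
        if adj is None:
            raise InputError(f"{name} requires a PriorAdjustment")
        if name == "lasce":
            return lambda z, y: lasce_loss(z, y, adj)
        return lambda z, y: la_focal_loss(z, y, adj, gamma)
    raise InputError(f"unknown loss {name!r}")
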