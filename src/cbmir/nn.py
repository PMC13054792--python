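"""Minimal layer-based neural-network framework (numpy, manual backprop).

The embedding model this package trains is small and feed-forward, so the
framework is deliberately compact: each layer caches what it needs in
``forward`` and returns the input gradient from ``backward``; an
:class:`SGD` optimizer with momentum updates the collected parameters.
Everything is float32 and purely numpy, which makes training bit-reproducible
for a fixed seed on a fixed platform.

The two operations that carry the retrieval method itself live here as both
layers and plain functions:

* **Generalized-mean (GeM) pooling** — for channel k with spatial
  activations X_k, ``f_k = (mean(x^p for x in X_k))^(1/p)``.  ``p = 1``
  recovers average pooling and ``p → ∞`` approaches max pooling; the power
  mean is non-decreasing in p.  ``p`` is a fixed constant (default 3),
  shared across channels and non-trainable.
* **ArcFace loss** — cross-entropy over angularly re-margined cosine logits:
  the true-class logit is ``s·cos(θ_y + m)`` and the others ``s·cos θ_j``,
  with embeddings and class-weight rows L2-normalized before the angle is
  computed.  ``m = 0`` reduces exactly to softmax cross-entropy on
  ``s·cos θ`` logits.  Cosines are clamped away from ±1 before arccos, and
  when ``θ_y + m`` would exceed π the standard easy-margin surrogate
  ``cos θ_y − m·sin(m)`` is used, where the adjusted logit is otherwise
  undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "BatchNorm1d",
    "ReLU",
    "PReLU",
    "AvgPool2d",
    "Linear",
    "GeMPool",
    "Concat",
    "gem_pool",
    "ArcFaceParams",
    "ArcFaceHead",
    "arcface_loss",
    "l2_normalize",
    "SGD",
]

_F32 = np.float32


class Param:
    """A trainable tensor with its gradient and momentum buffer."""

    __slots__ = ("value", "grad", "velocity", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=_F32)
        self.grad = np.zeros_like(self.value)
        self.velocity = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
            if grad is None:  # earliest trainable layer reached; stop
                break
        return grad


class Conv2d(Layer):
    """2-D convolution via im2col; input layout (N, C, H, W)."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, stride: int = 1, pad: int = 0, rng=None,
                 input_grad: bool = True):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * ksize * ksize
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.weight = Param(w, "conv.weight")
        self.bias = Param(np.zeros(out_ch), "conv.bias")
        self.ksize, self.stride, self.pad = ksize, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        # input_grad=False marks the network's earliest trainable layer: its
        # input gradient is never consumed, so col2im can be skipped
        self.input_grad = input_grad
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        # convolution as a tensor contraction over a strided window view:
        # no explicit im2col materialization
        x = np.ascontiguousarray(x, dtype=_F32)
        n, c, h, w = x.shape
        k, s, p = self.ksize, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (xp.shape[2] - k) // s + 1
        wo = (xp.shape[3] - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        w4 = self.weight.value.reshape(self.out_ch, c, k, k)
        out = np.tensordot(win, w4, axes=([1, 4, 5], [1, 2, 3]))  # (n, ho, wo, out)
        out += self.bias.value
        self._cache = (win, (n, c, h, w, ho, wo)) if train else None
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, grad):
        win, (n, c, h, w, ho, wo) = self._cache
        k, s, p = self.ksize, self.stride, self.pad
        w4 = self.weight.value.reshape(self.out_ch, c, k, k)
        # dW[o,c,i,j] = sum_{n,h,w} g[n,o,h,w] * win[n,c,h,w,i,j]
        dw = np.tensordot(grad, win, axes=([0, 2, 3], [0, 2, 3]))
        self.weight.grad += dw.reshape(self.out_ch, -1)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        if not self.input_grad:
            self._cache = None
            return None
        dcols = np.tensordot(grad, w4, axes=(1, 0))  # (n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cache = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class _BatchNorm(Layer):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(num_features), "bn.gamma")
        self.beta = Param(np.zeros(num_features), "bn.beta")
        self.running_mean = np.zeros(num_features, dtype=_F32)
        self.running_var = np.ones(num_features, dtype=_F32)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def _fwd2d(self, x2: np.ndarray, train: bool) -> np.ndarray:
        # x2: (M, C)
        if train:
            if x2.shape[0] < 2:
                raise ValueError("BatchNorm in train mode requires batch size >= 2")
            mu = x2.mean(axis=0)
            var = x2.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x2 - mu) / std
        if train:
            self._cache = (xhat, std)
        return self.gamma.value * xhat + self.beta.value

    def _bwd2d(self, g2: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        self.gamma.grad += (g2 * xhat).sum(axis=0)
        self.beta.grad += g2.sum(axis=0)
        m = g2.shape[0]
        dxhat = g2 * self.gamma.value
        dx = (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std
        self._cache = None
        return dx.astype(_F32, copy=False)


class BatchNorm2d(_BatchNorm):
    def forward(self, x, train=False):
        n, c, h, w = x.shape
        self._shape = x.shape
        x2 = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, c)
        out = self._fwd2d(x2, train)
        return np.ascontiguousarray(out.reshape(n, h, w, c).transpose(0, 3, 1, 2))

    def backward(self, grad):
        n, c, h, w = self._shape
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, c)
        dx = self._bwd2d(g2)
        return np.ascontiguousarray(dx.reshape(n, h, w, c).transpose(0, 3, 1, 2))


class BatchNorm1d(_BatchNorm):
    def forward(self, x, train=False):
        return self._fwd2d(np.asarray(x, dtype=_F32), train)

    def backward(self, grad):
        return self._bwd2d(grad)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0 if train else None
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask


class PReLU(Layer):
    """Parametric ReLU with a single learnable slope."""

    def __init__(self, init: float = 0.25):
        self.slope = Param(np.array([init]), "prelu.slope")
        self._cache = None

    def params(self):
        return [self.slope]

    def forward(self, x, train=False):
        if train:
            self._cache = x
        a = self.slope.value[0]
        return np.where(x > 0, x, a * x).astype(_F32, copy=False)

    def backward(self, grad):
        x = self._cache
        neg = x <= 0
        self.slope.grad += np.array([float((grad * x * neg).sum())], dtype=_F32)
        self._cache = None
        return np.where(neg, self.slope.value[0] * grad, grad).astype(_F32, copy=False)


class AvgPool2d(Layer):
    """Non-overlapping average pooling (parameter-free)."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=False):
        s = self.size
        self._shape = x.shape
        out = x[:, :, ::s, ::s].astype(_F32, copy=True)
        for i in range(s):
            for j in range(s):
                if i or j:
                    out += x[:, :, i::s, j::s]
        out /= s * s
        return out

    def backward(self, grad):
        s = self.size
        g = np.empty(self._shape, dtype=_F32)
        gs = grad / (s * s)
        for i in range(s):
            for j in range(s):
                g[:, :, i::s, j::s] = gs
        return g


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng=None):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, math.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.weight = Param(w, "linear.weight")
        self.bias = Param(np.zeros(out_features), "linear.bias")
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=_F32)
        if x.shape[-1] != self.weight.value.shape[1]:
            raise ValueError(
                f"dimension mismatch: input has {x.shape[-1]} features, layer expects "
                f"{self.weight.value.shape[1]}"
            )
        if train:
            self._cache = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad):
        x = self._cache
        self.weight.grad += grad.T @ x
        self.bias.grad += grad.sum(axis=0)
        self._cache = None
        return grad @ self.weight.value


class GeMPool(Layer):
    """Generalized-mean pooling over spatial positions: (N,K,H,W) -> (N,K)."""

    def __init__(self, p: float = 3.0, eps: float = 1e-6):
        if p < 1:
            raise ValueError(f"GeM exponent p must be >= 1, got {p}")
        self.p, self.eps = float(p), float(eps)
        self._cache = None

    def forward(self, x, train=False):
        p = self.p
        xc = np.maximum(x, self.eps)
        y = (np.power(xc, p).mean(axis=(2, 3))) ** (1.0 / p)
        if train:
            self._cache = (x, xc, y)
        return y.astype(_F32, copy=False)

    def backward(self, grad):
        x, xc, y = self._cache
        p = self.p
        nhw = x.shape[2] * x.shape[3]
        coef = (grad * np.power(y, 1.0 - p))[:, :, None, None] / nhw
        dx = coef * np.power(xc, p - 1.0)
        dx[x < self.eps] = 0.0  # clamp region passes no gradient
        self._cache = None
        return dx.astype(_F32, copy=False)


class Concat(Layer):
    """Channel-wise concatenation of parallel branches (inception blocks)."""

    def __init__(self, *branches: Layer):
        self.branches = list(branches)

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def forward(self, x, train=False):
        outs = [b.forward(x, train=train) for b in self.branches]
        self._sizes = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, grad):
        dx = None
        start = 0
        for b, sz in zip(self.branches, self._sizes):
            g = b.backward(grad[:, start : start + sz])
            dx = g if dx is None else dx + g
            start += sz
        return dx


# ---------------------------------------------------------------------------
# Functional forms of the method's two core operations
# ---------------------------------------------------------------------------


def gem_pool(fmap: np.ndarray, p: float = 3.0, eps: float = 1e-6) -> np.ndarray:
    """GeM-pool a single feature map of shape (H, W, K) into a K-vector.

    ``f_k = (mean over spatial positions of x^p)^(1/p)`` with activations
    clamped at ``eps`` first (fractional powers of negatives are undefined;
    post-ReLU maps are non-negative anyway).
    """
    if p < 1:
        raise ValueError(f"GeM exponent p must be >= 1, got {p}")
    fmap = np.asarray(fmap, dtype=np.float64)
    if fmap.ndim == 2:
        fmap = fmap[:, :, None]
    if fmap.ndim != 3:
        raise ValueError(f"expected (H, W, K) feature map, got shape {fmap.shape}")
    xc = np.maximum(fmap, eps)
    # factor out the per-channel max so x^p cannot overflow for large p
    m = xc.max(axis=(0, 1))
    return m * (np.power(xc / m, p).mean(axis=(0, 1))) ** (1.0 / p)


def l2_normalize(x: np.ndarray, axis: int = -1, eps: float = 1e-12) -> np.ndarray:
    n = np.linalg.norm(x, axis=axis, keepdims=True)
    return x / np.maximum(n, eps)


@dataclass
class ArcFaceParams:
    """Additive-angular-margin head parameters.

    ``margin`` is given in degrees (converted internally to radians) with the
    conventional retrieval defaults: scale 64, margin 38°.
    """

    n_classes: int = 7
    dim: int = 256
    scale: float = 64.0
    margin_deg: float = 38.0
    weight: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not (0.0 <= self.margin <= math.pi):
            raise ValueError("margin must lie in [0, pi] radians")
        if self.weight is None:
            rng = np.random.default_rng(self.seed)
            w = rng.normal(0, 0.01, size=(self.n_classes, self.dim))
            self.weight = l2_normalize(w, axis=1).astype(_F32)
        else:
            self.weight = np.asarray(self.weight, dtype=_F32)
            if self.weight.shape != (self.n_classes, self.dim):
                raise ValueError("weight shape must be (n_classes, dim)")

    @property
    def margin(self) -> float:
        return math.radians(self.margin_deg)


_COS_CLAMP = 1.0 - 1e-7


def _arcface_core(emb_raw: np.ndarray, labels: np.ndarray, weight: np.ndarray, s: float, m: float):
    """Forward pass shared by the functional loss and the training head.

    Returns (loss, probs, cosines, intermediates-for-backward).
    """
    emb_raw = np.asarray(emb_raw, dtype=np.float64)
    labels = np.asarray(labels)
    n, dim = emb_raw.shape
    if labels.min() < 0 or labels.max() >= weight.shape[0]:
        raise ValueError("label outside [0, n_classes)")

    e_norm = np.linalg.norm(emb_raw, axis=1, keepdims=True)
    e = emb_raw / np.maximum(e_norm, 1e-12)
    w64 = np.asarray(weight, dtype=np.float64)
    w_norm = np.linalg.norm(w64, axis=1, keepdims=True)
    wn = w64 / np.maximum(w_norm, 1e-12)

    cos = np.clip(e @ wn.T, -_COS_CLAMP, _COS_CLAMP)  # (n, classes)
    cos_y = cos[np.arange(n), labels]
    sin_y = np.sqrt(1.0 - cos_y**2)
    cm, sm = math.cos(m), math.sin(m)
    phi = cos_y * cm - sin_y * sm  # cos(theta_y + m)
    # easy-margin fallback where theta_y + m > pi (phi no longer monotone)
    th = math.cos(math.pi - m)
    easy = cos_y <= th
    mm = math.sin(math.pi - m) * m
    phi = np.where(easy, cos_y - mm, phi)

    logits = s * cos
    logits[np.arange(n), labels] = s * phi
    zmax = logits.max(axis=1, keepdims=True)
    ez = np.exp(logits - zmax)
    sez = ez.sum(axis=1, keepdims=True)
    probs = ez / sez
    # log-sum-exp form of the negative log-likelihood
    nll = np.log(sez[:, 0]) - (logits[np.arange(n), labels] - zmax[:, 0])
    loss = float(nll.mean())
    cache = (e, wn, e_norm, w_norm, cos, cos_y, sin_y, easy, labels, s, cm, sm)
    return loss, probs, cache


def _arcface_backward(probs: np.ndarray, cache, emb_raw: np.ndarray):
    """Gradients of the mean loss w.r.t. raw embeddings and raw weight rows."""
    e, wn, e_norm, w_norm, cos, cos_y, sin_y, easy, labels, s, cm, sm = cache
    n = probs.shape[0]
    g = probs.copy()
    g[np.arange(n), labels] -= 1.0
    g *= s / n  # dL/dlogits * s
    # chain through phi for the target column
    dphi_dcos = cm + sm * cos_y / np.maximum(sin_y, 1e-7)
    dphi_dcos = np.where(easy, 1.0, dphi_dcos)
    g[np.arange(n), labels] *= dphi_dcos

    de = g @ wn  # (n, dim), grad wrt normalized embedding
    dwn = g.T @ e  # (classes, dim), grad wrt normalized weights
    # through L2 normalization
    demb = (de - e * (de * e).sum(axis=1, keepdims=True)) / np.maximum(e_norm, 1e-12)
    dweight = (dwn - wn * (dwn * wn).sum(axis=1, keepdims=True)) / np.maximum(w_norm, 1e-12)
    return demb.astype(_F32), dweight.astype(_F32)


def arcface_loss(embeddings: np.ndarray, labels, params: ArcFaceParams) -> float:
    """Mean ArcFace loss of a batch (functional, no gradients)."""
    loss, _, _ = _arcface_core(
        embeddings, np.asarray(labels), params.weight, params.scale, params.margin
    )
    return loss


class ArcFaceHead(Layer):
    """Trainable ArcFace classification head over raw (unnormalized) embeddings."""

    def __init__(self, params: ArcFaceParams):
        self.cfg = params
        self.weight = Param(params.weight, "arcface.weight")
        self._cache = None

    def params(self):
        return [self.weight]

    def loss(self, emb_raw: np.ndarray, labels: np.ndarray, train: bool = True):
        loss, probs, cache = _arcface_core(
            emb_raw, labels, self.weight.value, self.cfg.scale, self.cfg.margin
        )
        if train:
            self._cache = (probs, cache, emb_raw)
        return loss, probs

    def backward(self) -> np.ndarray:
        probs, cache, emb_raw = self._cache
        demb, dweight = _arcface_backward(probs, cache, emb_raw)
        self.weight.grad += dweight
        self._cache = None
        return demb

    def renormalize(self) -> None:
        """Project weight rows back to unit norm (called after each update)."""
        self.weight.value = l2_normalize(self.weight.value, axis=1).astype(_F32)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: Sequence[Param], lr: float = 0.01, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p in self.params:
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            p.velocity[...] = self.momentum * p.velocity + g
            p.value -= self.lr * p.velocity
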