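"""Minimal CNN building blocks with explicit forward/backward passes.

The toolkit needs full access to every intermediate tensor of the
classifier — activations for CAM weighting, gradients for GradCAM-style
baselines, and per-layer linear structure for relevance propagation.
A small, explicit numpy implementation gives all three on the same layer
objects, at the desk scale this toolkit targets (small images, small
channel counts).

Conventions: tensors are ``(N, C, H, W)`` float64, row-major, 0-based
``(row, col)`` indexing. Each layer caches the input of its most recent
forward pass (``layer.x``); backward passes and relevance rules read that
cache, so forward must precede either.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Layer", "Conv2d", "Linear", "ReLU", "BatchNorm2d", "MaxPool2d",
    "AvgPool2d", "GlobalAvgPool", "Flatten", "Dropout", "ResidualBlock",
    "ModelGraph", "AdaMax", "softmax", "cross_entropy",
]


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Unfold ``(N, C, H, W)`` into ``(N, C*kh*kw, oh*ow)`` patch columns."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    win = as_strided(
        xp,
        shape=(n, c, kh, kw, oh, ow),
        strides=(s0, s1, s2, s3, stride * s2, stride * s3),
    )
    return win.reshape(n, c * kh * kw, oh * ow).copy(), oh, ow


def col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Scatter-add patch columns back onto the ``(N, C, H, W)`` grid."""
    n, c, h, w = x_shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for i in range(kh):
        i_max = i + stride * oh
        for j in range(kw):
            j_max = j + stride * ow
            xp[:, :, i:i_max:stride, j:j_max:stride] += cols[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w]


class Layer:
    """Base layer: forward caches input, backward consumes the cache."""

    kind = "abstract"

    def forward(self, x, *, bn_train=False, dropout_on=False, rng=None):
        raise NotImplementedError

    def backward(self, gy):
        raise NotImplementedError

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def init_params(self, rng: np.random.Generator) -> None:
        pass


class Conv2d(Layer):
    kind = "conv"

    def __init__(self, in_ch, out_ch, ksize=3, stride=1, pad=1, bias=True):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.ksize, self.stride, self.pad = ksize, stride, pad
        self.has_bias = bias
        self.W = np.zeros((out_ch, in_ch, ksize, ksize))
        self.b = np.zeros(out_ch) if bias else None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros(out_ch) if bias else None
        self.x = None
        self._cols = None

    def init_params(self, rng):
        fan_in = self.in_ch * self.ksize * self.ksize
        self.W = _he_normal(rng, self.W.shape, fan_in)
        if self.has_bias:
            self.b = np.zeros(self.out_ch)

    def params(self):
        p = {"W": self.W}
        if self.has_bias:
            p["b"] = self.b
        return p

    def grads(self):
        g = {"W": self.gW}
        if self.has_bias:
            g["b"] = self.gb
        return g

    def apply(self, x, W, b):
        """Convolve ``x`` with arbitrary weights (used for folded BN weights)."""
        cols, oh, ow = im2col(x, self.ksize, self.ksize, self.stride, self.pad)
        wf = W.reshape(W.shape[0], -1)
        y = np.einsum("ok,nkp->nop", wf, cols)
        if b is not None:
            y += b[None, :, None]
        return y.reshape(x.shape[0], W.shape[0], oh, ow)

    def input_grad(self, gy, W):
        """Gradient of ``apply`` w.r.t. its input, for arbitrary weights."""
        n = gy.shape[0]
        wf = W.reshape(W.shape[0], -1)
        gcols = np.einsum("ok,nop->nkp", wf, gy.reshape(n, W.shape[0], -1))
        return col2im(gcols, self.x.shape, self.ksize, self.ksize,
                      self.stride, self.pad)

    def forward(self, x, **kw):
        self.x = x
        cols, oh, ow = im2col(x, self.ksize, self.ksize, self.stride, self.pad)
        self._cols = cols
        wf = self.W.reshape(self.out_ch, -1)
        y = np.einsum("ok,nkp->nop", wf, cols)
        if self.has_bias:
            y += self.b[None, :, None]
        return y.reshape(x.shape[0], self.out_ch, oh, ow)

    def backward(self, gy):
        n = gy.shape[0]
        gyf = gy.reshape(n, self.out_ch, -1)
        self.gW += np.einsum("nop,nkp->ok", gyf, self._cols).reshape(self.W.shape)
        if self.has_bias:
            self.gb += gyf.sum(axis=(0, 2))
        return self.input_grad(gy, self.W)


class Linear(Layer):
    kind = "linear"

    def __init__(self, in_features, out_features, bias=True):
        self.in_features, self.out_features = in_features, out_features
        self.has_bias = bias
        self.W = np.zeros((out_features, in_features))
        self.b = np.zeros(out_features) if bias else None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros(out_features) if bias else None
        self.x = None

    def init_params(self, rng):
        self.W = _he_normal(rng, self.W.shape, self.in_features)
        if self.has_bias:
            self.b = np.zeros(self.out_features)

    def params(self):
        p = {"W": self.W}
        if self.has_bias:
            p["b"] = self.b
        return p

    def grads(self):
        g = {"W": self.gW}
        if self.has_bias:
            g["b"] = self.gb
        return g

    def forward(self, x, **kw):
        self.x = x
        y = x @ self.W.T
        if self.has_bias:
            y += self.b
        return y

    def backward(self, gy):
        self.gW += gy.T @ self.x
        if self.has_bias:
            self.gb += gy.sum(axis=0)
        return gy @ self.W


class ReLU(Layer):
    kind = "relu"

    def forward(self, x, **kw):
        self.x = x
        return np.maximum(x, 0.0)

    def backward(self, gy):
        return gy * (self.x > 0)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    ``bn_train=True`` uses batch statistics and updates running moments;
    otherwise the layer is a fixed per-channel affine map (which is what
    the relevance propagation folds into the preceding convolution).
    """

    kind = "batchnorm"

    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        self.num_features = num_features
        self.momentum, self.eps = momentum, eps
        self.gamma = np.ones(num_features)
        self.beta = np.zeros(num_features)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.ggamma = np.zeros(num_features)
        self.gbeta = np.zeros(num_features)
        self.x = None
        self._train_cache = None

    def init_params(self, rng):
        self.gamma = np.ones(self.num_features)
        self.beta = np.zeros(self.num_features)
        self.running_mean = np.zeros(self.num_features)
        self.running_var = np.ones(self.num_features)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.ggamma, "beta": self.gbeta}

    def effective_scale_shift(self):
        """Eval-mode affine: y = scale * x + shift, per channel."""
        scale = self.gamma / np.sqrt(self.running_var + self.eps)
        shift = self.beta - self.running_mean * scale
        return scale, shift

    def forward(self, x, *, bn_train=False, **kw):
        self.x = x
        if bn_train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._train_cache = (xhat, inv)
            return (self.gamma[None, :, None, None] * xhat
                    + self.beta[None, :, None, None])
        self._train_cache = None
        scale, shift = self.effective_scale_shift()
        return scale[None, :, None, None] * x + shift[None, :, None, None]

    def backward(self, gy):
        if self._train_cache is None:
            scale, _ = self.effective_scale_shift()
            self.gbeta += gy.sum(axis=(0, 2, 3))
            # xhat in eval mode for gamma grad
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (self.x - self.running_mean[None, :, None, None]) \
                * inv[None, :, None, None]
            self.ggamma += (gy * xhat).sum(axis=(0, 2, 3))
            return gy * scale[None, :, None, None]
        xhat, inv = self._train_cache
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        self.gbeta += gy.sum(axis=(0, 2, 3))
        self.ggamma += (gy * xhat).sum(axis=(0, 2, 3))
        gxhat = gy * self.gamma[None, :, None, None]
        gx = (gxhat
              - gxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return gx * inv[None, :, None, None]


class MaxPool2d(Layer):
    kind = "maxpool"

    def __init__(self, ksize=2):
        self.ksize = ksize
        self.x = None
        self._argmax = None

    def forward(self, x, **kw):
        self.x = x
        n, c, h, w = x.shape
        k = self.ksize
        xr = x.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // k, w // k, k * k)
        self._argmax = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def route(self, r):
        """Send each output value to its winning input position."""
        n, c, oh, ow = r.shape
        k = self.ksize
        out = np.zeros((n, c, oh, ow, k * k))
        np.put_along_axis(out, self._argmax[..., None], r[..., None], axis=-1)
        out = out.reshape(n, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(self.x.shape)

    def backward(self, gy):
        return self.route(gy)


class AvgPool2d(Layer):
    kind = "avgpool"

    def __init__(self, ksize=2):
        self.ksize = ksize
        self.x = None

    def forward(self, x, **kw):
        self.x = x
        n, c, h, w = x.shape
        k = self.ksize
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def spread(self, r):
        k = self.ksize
        return np.repeat(np.repeat(r, k, axis=2), k, axis=3) / (k * k)

    def backward(self, gy):
        return self.spread(gy)


class GlobalAvgPool(Layer):
    kind = "global_pool"

    def forward(self, x, **kw):
        self.x = x
        return x.mean(axis=(2, 3), keepdims=True)

    def backward(self, gy):
        n, c, h, w = self.x.shape
        return np.broadcast_to(gy, self.x.shape) / (h * w)


class Flatten(Layer):
    kind = "flatten"

    def forward(self, x, **kw):
        self.x = x
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self.x.shape)


class Dropout(Layer):
    """Inverted dropout; active only when the pass requests it."""

    kind = "dropout"

    def __init__(self, rate):
        self.rate = float(rate)
        self.x = None
        self._mask = None

    def forward(self, x, *, dropout_on=False, rng=None, **kw):
        self.x = x
        if dropout_on and self.rate > 0:
            if rng is None:
                raise ValueError("stochastic dropout pass requires an rng")
            self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class ResidualBlock(Layer):
    """y = x + F(x), with F a short conv branch. Output caches both addends."""

    kind = "residual_add"

    def __init__(self, branch: list[Layer]):
        self.branch = branch
        self.x = None
        self.branch_out = None

    def init_params(self, rng):
        for lyr in self.branch:
            lyr.init_params(rng)

    def params(self):
        return {f"branch{i}.{k}": v for i, lyr in enumerate(self.branch)
                for k, v in lyr.params().items()}

    def grads(self):
        return {f"branch{i}.{k}": v for i, lyr in enumerate(self.branch)
                for k, v in lyr.grads().items()}

    def forward(self, x, **kw):
        self.x = x
        h = x
        for lyr in self.branch:
            h = lyr.forward(h, **kw)
        self.branch_out = h
        return x + h

    def backward(self, gy):
        g = gy
        for lyr in reversed(self.branch):
            g = lyr.backward(g)
        return gy + g


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits, labels):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return loss, g / n


class ModelGraph:
    """Ordered layer list with named stages ``layer1..layer4``.

    ``stage_boundaries`` maps each stage name to the index of the layer
    whose *output* is that stage's feature map — the tensor read by the
    CAM weightings and by the relevance propagation.
    """

    STAGES = ("layer1", "layer2", "layer3", "layer4")

    def __init__(self, layers: list[Layer], stage_boundaries: dict[str, int],
                 n_classes: int, input_shape: tuple[int, int, int]):
        if tuple(stage_boundaries) != self.STAGES:
            raise ValueError("expected stages layer1..layer4 in order")
        idx = list(stage_boundaries.values())
        if idx != sorted(idx):
            raise ValueError("stage boundaries must be increasing")
        if layers[-1].kind != "linear":
            raise ValueError("last layer must be the linear head")
        self.layers = layers
        self.stage_boundaries = dict(stage_boundaries)
        self.n_classes = int(n_classes)
        self.input_shape = tuple(input_shape)

    # -- forward ---------------------------------------------------------

    def forward(self, x, *, bn_train=False, dropout_on=False, rng=None,
                capture=False):
        """Run the network; optionally record stage activations.

        Returns logits, or ``(logits, {stage: activation})`` if capturing.
        """
        boundary_of = {v: k for k, v in self.stage_boundaries.items()}
        acts = {}
        h = x
        for i, lyr in enumerate(self.layers):
            h = lyr.forward(h, bn_train=bn_train, dropout_on=dropout_on,
                            rng=rng)
            if capture and i in boundary_of:
                acts[boundary_of[i]] = h.copy()
        return (h, acts) if capture else h

    def forward_from(self, stage: str, activation: np.ndarray):
        """Resume the forward pass from a stage's output activation.

        Deterministic continuation: dropout inactive, BN in eval mode.
        Does not disturb cached inputs of layers at or below the stage
        only insofar as layers above the stage are re-run (their caches
        are overwritten — capture again if needed).
        """
        start = self.stage_boundaries[stage] + 1
        h = activation
        for lyr in self.layers[start:]:
            h = lyr.forward(h)
        return h

    # -- backward --------------------------------------------------------

    def zero_grads(self):
        for lyr in self.layers:
            for g in lyr.grads().values():
                g[...] = 0.0

    def backward(self, glogits, capture=False):
        """Backpropagate; optionally record gradients at stage outputs."""
        boundary_of = {v: k for k, v in self.stage_boundaries.items()}
        grads = {}
        g = glogits
        for i in range(len(self.layers) - 1, -1, -1):
            if capture and i in boundary_of:
                grads[boundary_of[i]] = g.copy()
            g = self.layers[i].backward(g)
        return (g, grads) if capture else g

    # -- parameter access ------------------------------------------------

    def named_params(self):
        return {f"layer{i}.{k}": v for i, lyr in enumerate(self.layers)
                for k, v in lyr.params().items()}

    def named_grads(self):
        return {f"layer{i}.{k}": v for i, lyr in enumerate(self.layers)
                for k, v in lyr.grads().items()}

    def get_weights(self):
        return {k: v.copy() for k, v in self.named_params().items()}

    def set_weights(self, weights):
        params = self.named_params()
        if set(weights) != set(params):
            raise ValueError("weight dictionary does not match topology")
        for k, v in params.items():
            v[...] = weights[k]

    def zero_biases(self):
        """Zero every additive term (conv/linear bias, BN shift and mean).

        After this the network is a positively-homogeneous map, for which
        the relevance rules conserve exactly.
        """
        def _zero(lyr):
            if isinstance(lyr, (Conv2d, Linear)) and lyr.has_bias:
                lyr.b[...] = 0.0
            if isinstance(lyr, BatchNorm2d):
                lyr.beta[...] = 0.0
                lyr.running_mean[...] = 0.0
            if isinstance(lyr, ResidualBlock):
                for sub in lyr.branch:
                    _zero(sub)
        for lyr in self.layers:
            _zero(lyr)


class AdaMax:
    """AdaMax optimizer (infinity-norm Adam variant)."""

    def __init__(self, model: ModelGraph, lr=0.001, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.named_params().items()}
        self.u = {k: np.zeros_like(v) for k, v in model.named_params().items()}

    def step(self):
        self.t += 1
        params = self.model.named_params()
        grads = self.model.named_grads()
        bc = 1.0 - self.beta1 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.u[k] = np.maximum(self.beta2 * self.u[k], np.abs(g))
            p -= (self.lr / bc) * self.m[k] / (self.u[k] + self.eps)
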