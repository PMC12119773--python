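"""Minimal CNN framework (numpy, manual backprop) for the desk-scale models.

Layers operate on (N, C, H, W) float64 tensors. Each trainable layer stores its
parameter gradients after ``backward``; :class:`Adam` updates parameters in
place. ``Sequential.forward(..., cache=True)`` retains every layer output so
GradCAM can request the gradient at an interior layer.

Kept intentionally small: convolution via im2col, ReLU, 2x2 max pooling,
nearest upsampling, global average pooling, dense, plus softmax cross-entropy
and Dice+BCE losses with analytic gradients.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    trainable = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self):
        return []


class Conv2D(Layer):
    """Same-padded 2D convolution with odd square kernels, stride 1."""

    trainable = True

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        assert k % 2 == 1
        self.cin, self.cout, self.k = cin, cout, k
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0.0, std, size=(cout, cin * k * k))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # n,c,h,w,k,k
        cols = win.reshape(n, c, h * w, k * k).transpose(0, 1, 3, 2)
        cols = np.ascontiguousarray(cols).reshape(n, c * k * k, h * w)
        self._cols, self._shape = cols, (n, c, h, w)
        y = np.matmul(self.W[None], cols) + self.b[None, :, None]
        return y.reshape(n, self.cout, h, w)

    def backward(self, g):
        n, c, h, w = self._shape
        k, p = self.k, self.k // 2
        gf = g.reshape(n, self.cout, h * w)
        self.dW += np.einsum("nop,nfp->of", gf, self._cols)
        self.db += gf.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T[None], gf)  # n, c*k*k, h*w
        dcols = dcols.reshape(n, c, k * k, h, w)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for idx in range(k * k):
            di, dj = divmod(idx, k)
            dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, idx]
        return dxp[:, :, p : p + h, p : p + w]

    def params(self):
        return [(self, "W", "dW"), (self, "b", "db")]


class InstanceNorm2D(Layer):
    """Per-sample, per-channel normalization with learned scale and shift."""

    trainable = True

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.gamma[None, :, None, None] + self.beta[None, :, None, None]

    def backward(self, g):
        xhat, inv = self._xhat, self._inv
        self.dgamma += (g * xhat).sum(axis=(0, 2, 3))
        self.dbeta += g.sum(axis=(0, 2, 3))
        gx = g * self.gamma[None, :, None, None]
        return inv * (
            gx
            - gx.mean(axis=(2, 3), keepdims=True)
            - xhat * (gx * xhat).mean(axis=(2, 3), keepdims=True)
        )

    def params(self):
        return [(self, "gamma", "dgamma"), (self, "beta", "dbeta")]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input H and W must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        assert h % 2 == 0 and w % 2 == 0, "MaxPool2 requires even spatial dims"
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._inshape = (n, c, h, w)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, c, h, w = self._inshape
        gr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(gr, self._idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gr.reshape(n, c, h, w)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g):
        n, c, h, w = g.shape
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        n, c, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None] / (h * w), self._shape).copy()


class Dense(Layer):
    trainable = True

    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / fin), size=(fin, fout))
        self.b = np.zeros(fout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW += self._x.T @ g
        self.db += g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self, "W", "dW"), (self, "b", "db")]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.outputs: list[np.ndarray] | None = None

    def forward(self, x, cache: bool = False):
        outs = []
        for layer in self.layers:
            x = layer.forward(x)
            if cache:
                outs.append(x)
        self.outputs = outs if cache else None
        return x

    def backward(self, g, collect: bool = False):
        """Backpropagate; optionally return the gradient w.r.t. every layer output."""
        grads = [None] * len(self.layers) if collect else None
        for i in range(len(self.layers) - 1, -1, -1):
            if collect:
                grads[i] = g
            g = self.layers[i].backward(g)
        return (g, grads) if collect else g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def zero_grads(self):
        for obj, _, gname in self.params():
            getattr(obj, gname)[...] = 0.0

    def get_state(self):
        return [getattr(obj, pname).copy() for obj, pname, _ in self.params()]

    def set_state(self, state):
        for (obj, pname, _), value in zip(self.params(), state):
            getattr(obj, pname)[...] = value


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(o, p)) for o, p, _ in model.params()]
        self.v = [np.zeros_like(getattr(o, p)) for o, p, _ in model.params()]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (obj, pname, gname) in enumerate(self.model.params()):
            g = getattr(obj, gname)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            getattr(obj, pname)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        self.model.zero_grads()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def dice_bce_loss(logits: np.ndarray, targets: np.ndarray, eps: float = 1.0,
                  pos_weight: float | None = None):
    """Dice + binary cross-entropy on (N,1,H,W) logits; returns (loss, dlogits).

    ``pos_weight`` up-weights foreground pixels in the BCE term (``None``
    derives it from the batch as background/foreground ratio, capped at 20) so
    small structures are not drowned out early in training.
    """
    n = logits.shape[0]
    p = 1.0 / (1.0 + np.exp(-logits))
    t = targets.astype(np.float64)
    npix = logits[0].size
    if pos_weight is None:
        n_fg = t.sum()
        pos_weight = min(20.0, (t.size - n_fg) / max(n_fg, 1.0))
    wgt = 1.0 + (pos_weight - 1.0) * t
    norm = n * npix
    bce = -(wgt * (t * np.log(np.clip(p, 1e-12, None))
                   + (1 - t) * np.log(np.clip(1 - p, 1e-12, None)))).sum() / norm
    dbce_dp = wgt * (-(t / np.clip(p, 1e-12, None))
                     + (1 - t) / np.clip(1 - p, 1e-12, None)) / norm
    axes = (1, 2, 3)
    inter = (p * t).sum(axis=axes)
    denom = p.sum(axis=axes) + t.sum(axis=axes)
    dice = (2 * inter + eps) / (denom + eps)
    loss_dice = (1.0 - dice).mean()
    ddice_dp = (2 * t * (denom + eps)[:, None, None, None]
                - (2 * inter + eps)[:, None, None, None]) / (
        (denom + eps) ** 2
    )[:, None, None, None]
    dloss_dp = dbce_dp - ddice_dp / n
    dp_dz = p * (1 - p)
    return bce + loss_dice, dloss_dp * dp_dz


def make_small_cnn(rng: np.random.Generator, in_channels: int = 1,
                   n_classes: int = 2) -> Sequential:
    """3-conv-block classifier with global average pooling (``cnn_small``)."""
    return Sequential([
        Conv2D(in_channels, 8, 3, rng), InstanceNorm2D(8), ReLU(), MaxPool2(),
        Conv2D(8, 16, 3, rng), InstanceNorm2D(16), ReLU(), MaxPool2(),
        Conv2D(16, 32, 3, rng), InstanceNorm2D(32), ReLU(), MaxPool2(),
        GlobalAvgPool(), Dense(32, n_classes, rng),
    ])


def make_small_segnet(rng: np.random.Generator, in_channels: int = 1) -> Sequential:
    """Full-resolution convolutional segmenter (``unet_small``).

    No down/upsampling: boundaries stay sharp on the small phantom images and
    the ~15-pixel receptive field (~42 mm at 2.8 mm spacing) covers enough
    context to separate the heart from ribs and abdominal organs.
    """
    return Sequential([
        Conv2D(in_channels, 8, 7, rng), InstanceNorm2D(8), ReLU(),
        Conv2D(8, 16, 5, rng), InstanceNorm2D(16), ReLU(),
        Conv2D(16, 8, 3, rng), InstanceNorm2D(8), ReLU(),
        Conv2D(8, 1, 3, rng),
    ])
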