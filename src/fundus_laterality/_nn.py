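"""Minimal numpy neural-network engine used by the laterality classifier.

Implements exactly the layer vocabulary the two backbones need — 2-D
convolution (via im2col), ReLU, max/average pooling, channel-concatenated
branches, global average pooling and a final affine head — each with a
hand-written backward pass, so training runs on a plain CPU with no
deep-learning framework.  All state lives in :class:`Param` objects;
layers are stateless apart from caches kept between ``forward`` and
``backward`` of the same step.

Arrays are NCHW ``float32`` throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "AvgPool2d",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "Branches",
    "Network",
    "softmax",
]


class Param:
    """A trainable tensor with an accumulated gradient.

    ``decay`` marks parameters subject to L2 weight decay (convolution and
    affine weights); biases are exempt.
    """

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    training: bool = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def children(self) -> list["Layer"]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state included in weight snapshots (e.g. BN statistics)."""
        return []


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def _windows(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """View of shape (N, C, OH, OW, KH, KW) over a padded NCHW array."""
    n, c, h, w = xp.shape
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    sn, sc, sy, sx = xp.strides
    return as_strided(
        xp,
        shape=(n, c, oh, ow, kh, kw),
        strides=(sn, sc, sy * sh, sx * sw, sy, sx),
        writeable=False,
    )


def _col2im(dcols: np.ndarray, x_shape, kh, kw, sh, sw, ph, pw) -> np.ndarray:
    """Scatter-add window gradients (N, C, OH, OW, KH, KW) back to NCHW."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * ph, w + 2 * pw
    oh = (hp - kh) // sh + 1
    ow = (wp - kw) // sw + 1
    dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += dcols[:, :, :, :, i, j]
    return dxp[:, :, ph : ph + h, pw : pw + w]


class Conv2d(Layer):
    """Cross-correlation with bias; He-normal initialized."""

    def __init__(self, cin, cout, kernel, stride=1, pad=0, *, rng: np.random.Generator):
        self.kh, self.kw = _pair(kernel)
        self.sh, self.sw = _pair(stride)
        self.ph, self.pw = _pair(pad)
        fan_in = cin * self.kh * self.kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, self.kh, self.kw))
        self.w = Param(w.astype(np.float32), decay=True)
        self.b = Param(np.zeros(cout, dtype=np.float32), decay=False)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        win = _windows(xp, self.kh, self.kw, self.sh, self.sw)
        n, c, oh, ow = win.shape[0], win.shape[1], win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * oh * ow, c * self.kh * self.kw
        )
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)
        out = cols @ wmat.T + self.b.value
        self._cache = (cols, x.shape, (n, oh, ow))
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, (n, oh, ow) = self._cache
        cout = dy.shape[1]
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, cout)
        self.w.grad += (dyf.T @ cols).reshape(self.w.value.shape)
        self.b.grad += dyf.sum(axis=0)
        dcols = dyf @ self.w.value.reshape(cout, -1)
        c = x_shape[1]
        dcols = dcols.reshape(n, oh, ow, c, self.kh, self.kw).transpose(0, 3, 1, 2, 4, 5)
        self._cache = None
        return _col2im(dcols, x_shape, self.kh, self.kw, self.sh, self.sw, self.ph, self.pw)

    def params(self):
        return [self.w, self.b]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference.

    Gamma/beta are trainable but exempt from L2 decay; running mean/var are
    snapshot buffers.  The first training batch seeds the running statistics
    directly so early-epoch validation is not biased toward the (0, 1) init.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = Param(np.ones(channels, dtype=np.float32), decay=False)
        self.beta = Param(np.zeros(channels, dtype=np.float32), decay=False)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._initialized = np.zeros(1, dtype=np.float32)  # buffer: 0/1 flag
        self.eps = eps
        self.momentum = momentum

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self._initialized[0] == 0.0:
                self.running_mean[...] = mean
                self.running_var[...] = var
                self._initialized[0] = 1.0
            else:
                self.running_mean[...] = (
                    self.momentum * self.running_mean + (1 - self.momentum) * mean
                )
                self.running_var[...] = (
                    self.momentum * self.running_var + (1 - self.momentum) * var
                )
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if self.training:
            self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dy):
        xhat, inv = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[None, :, None, None] * inv[None, :, None, None]
        return g * (
            dy
            - dbeta[None, :, None, None] / m
            - xhat * dgamma[None, :, None, None] / m
        )

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var, self._initialized]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel, stride=None, pad=0):
        self.kh, self.kw = _pair(kernel)
        self.sh, self.sw = _pair(stride if stride is not None else kernel)
        self.ph, self.pw = _pair(pad)

    def forward(self, x):
        xp = np.pad(
            x,
            ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)),
            constant_values=-np.inf,
        )
        win = _windows(xp, self.kh, self.kw, self.sh, self.sw)
        n, c, oh, ow = win.shape[:4]
        flat = win.reshape(n, c, oh, ow, -1)
        self._argmax = flat.argmax(axis=-1)
        self._x_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy):
        n, c, oh, ow = dy.shape
        dcols = np.zeros((n, c, oh, ow, self.kh * self.kw), dtype=np.float32)
        np.put_along_axis(dcols, self._argmax[..., None], dy[..., None], axis=-1)
        dcols = dcols.reshape(n, c, oh, ow, self.kh, self.kw)
        return _col2im(
            dcols, self._x_shape, self.kh, self.kw, self.sh, self.sw, self.ph, self.pw
        )


class AvgPool2d(Layer):
    def __init__(self, kernel, stride=1, pad=0):
        self.kh, self.kw = _pair(kernel)
        self.sh, self.sw = _pair(stride)
        self.ph, self.pw = _pair(pad)

    def forward(self, x):
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        win = _windows(xp, self.kh, self.kw, self.sh, self.sw)
        self._x_shape = x.shape
        return win.mean(axis=(4, 5))

    def backward(self, dy):
        k = self.kh * self.kw
        dcols = np.broadcast_to(
            (dy / k)[..., None, None], dy.shape + (self.kh, self.kw)
        ).astype(np.float32)
        return _col2im(
            dcols, self._x_shape, self.kh, self.kw, self.sh, self.sw, self.ph, self.pw
        )


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._shape).astype(
            np.float32
        )


class Linear(Layer):
    def __init__(self, cin, cout, *, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cout, cin))
        self.w = Param(w.astype(np.float32), decay=True)
        self.b = Param(np.zeros(cout, dtype=np.float32), decay=False)

    def forward(self, x):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value

    def params(self):
        return [self.w, self.b]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def children(self):
        return self.layers


class Branches(Layer):
    """Parallel sub-networks concatenated along the channel axis (inception block)."""

    def __init__(self, branches: list[Layer]):
        self.branches = branches

    def forward(self, x):
        outs = [b.forward(x) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        parts = np.split(dy, self._splits, axis=1)
        dx = None
        for branch, part in zip(self.branches, parts):
            g = branch.backward(np.ascontiguousarray(part))
            dx = g if dx is None else dx + g
        return dx

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def children(self):
        return self.branches


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """Convolutional feature extractor + global average pooling + affine head.

    The GAP-before-affine structure is a hard requirement: it is what makes
    the class activation map a plain weighted sum of the last convolutional
    layer's feature maps.
    """

    gap_head = True

    def __init__(self, features: Sequential, head: Linear, input_side: int, name: str):
        self.features = features
        self.gap = GlobalAvgPool()
        self.head = head
        self.input_side = int(input_side)
        self.name = name

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits of shape (N, 2) for an NCHW batch."""
        return self.head.forward(self.gap.forward(self.features.forward(x)))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.features.backward(self.gap.backward(self.head.backward(dlogits)))

    def feature_maps(self, x: np.ndarray) -> np.ndarray:
        """Last-conv-layer activations (N, K, H', W') in inference mode."""
        self.set_training(False)
        return self.features.forward(x)

    def params(self) -> list[Param]:
        return self.features.params() + self.head.params()

    def _all_layers(self) -> list[Layer]:
        out, stack = [], [self.features, self.head]
        while stack:
            layer = stack.pop()
            out.append(layer)
            stack.extend(layer.children())
        return out

    def set_training(self, flag: bool) -> None:
        for layer in self._all_layers():
            layer.training = flag

    def buffers(self) -> list[np.ndarray]:
        return [b for layer in self._all_layers() for b in layer.buffers()]

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # -- weight snapshots (trainable params + BN statistics) ---------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()] + [
            b.copy() for b in self.buffers()
        ]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        buffers = self.buffers()
        if len(weights) != len(params) + len(buffers):
            raise ValueError("weight list does not match the network's parameters")
        for p, w in zip(params, weights):
            if w.shape != p.value.shape:
                raise ValueError("weight shape mismatch in snapshot")
            p.value[...] = w
        for b, w in zip(buffers, weights[len(params) :]):
            if w.shape != b.shape:
                raise ValueError("buffer shape mismatch in snapshot")
            b[...] = w


# ---------------------------------------------------------------------------
# Backbones
# ---------------------------------------------------------------------------


def _conv_relu(cin, cout, kernel, stride=1, pad=0, *, rng) -> Sequential:
    return Sequential([Conv2d(cin, cout, kernel, stride, pad, rng=rng), ReLU()])


def build_tiny(input_side: int, rng: np.random.Generator) -> Network:
    """Four conv/BN blocks (max-pool after the first two) ending in 32 maps.

    Batch normalization after each convolution keeps training stable at the
    aggressive initial learning rate the self-adaptive schedule starts from.
    The last conv layer sees a ~26-pixel receptive field on a quarter-
    resolution grid: wide enough to cover the optic disc together with its
    rim surround (the laterality cue), deliberately narrower than the
    disc-to-macula span, which keeps class activation maps anchored on the
    disc rather than the image center.
    """
    if input_side < 16:
        raise ValueError("tiny backbone needs input_side >= 16")
    features = Sequential(
        [
            Conv2d(3, 8, 3, pad=1, rng=rng),
            BatchNorm2d(8),
            ReLU(),
            MaxPool2d(2),
            Conv2d(8, 16, 3, pad=1, rng=rng),
            BatchNorm2d(16),
            ReLU(),
            MaxPool2d(2),
            Conv2d(16, 32, 3, pad=1, rng=rng),
            BatchNorm2d(32),
            ReLU(),
            Conv2d(32, 32, 3, pad=1, rng=rng),
            BatchNorm2d(32),
            ReLU(),
        ]
    )
    head = Linear(32, 2, rng=rng)
    return Network(features, head, input_side, "tiny")


def _inception_a(cin, pool_features, rng) -> Branches:
    return Branches(
        [
            _conv_relu(cin, 64, 1, rng=rng),
            Sequential(
                [*_conv_relu(cin, 48, 1, rng=rng).layers, *_conv_relu(48, 64, 5, pad=2, rng=rng).layers]
            ),
            Sequential(
                [
                    *_conv_relu(cin, 64, 1, rng=rng).layers,
                    *_conv_relu(64, 96, 3, pad=1, rng=rng).layers,
                    *_conv_relu(96, 96, 3, pad=1, rng=rng).layers,
                ]
            ),
            Sequential([AvgPool2d(3, 1, 1), *_conv_relu(cin, pool_features, 1, rng=rng).layers]),
        ]
    )


def _reduction_a(cin, rng) -> Branches:
    return Branches(
        [
            _conv_relu(cin, 384, 3, stride=2, rng=rng),
            Sequential(
                [
                    *_conv_relu(cin, 64, 1, rng=rng).layers,
                    *_conv_relu(64, 96, 3, pad=1, rng=rng).layers,
                    *_conv_relu(96, 96, 3, stride=2, rng=rng).layers,
                ]
            ),
            MaxPool2d(3, 2),
        ]
    )


def _inception_b(cin, c7, rng) -> Branches:
    return Branches(
        [
            _conv_relu(cin, 192, 1, rng=rng),
            Sequential(
                [
                    *_conv_relu(cin, c7, 1, rng=rng).layers,
                    *_conv_relu(c7, c7, (1, 7), pad=(0, 3), rng=rng).layers,
                    *_conv_relu(c7, 192, (7, 1), pad=(3, 0), rng=rng).layers,
                ]
            ),
            Sequential(
                [
                    *_conv_relu(cin, c7, 1, rng=rng).layers,
                    *_conv_relu(c7, c7, (7, 1), pad=(3, 0), rng=rng).layers,
                    *_conv_relu(c7, c7, (1, 7), pad=(0, 3), rng=rng).layers,
                    *_conv_relu(c7, c7, (7, 1), pad=(3, 0), rng=rng).layers,
                    *_conv_relu(c7, 192, (1, 7), pad=(0, 3), rng=rng).layers,
                ]
            ),
            Sequential([AvgPool2d(3, 1, 1), *_conv_relu(cin, 192, 1, rng=rng).layers]),
        ]
    )


def _reduction_b(cin, rng) -> Branches:
    return Branches(
        [
            Sequential(
                [
                    *_conv_relu(cin, 192, 1, rng=rng).layers,
                    *_conv_relu(192, 320, 3, stride=2, rng=rng).layers,
                ]
            ),
            Sequential(
                [
                    *_conv_relu(cin, 192, 1, rng=rng).layers,
                    *_conv_relu(192, 192, (1, 7), pad=(0, 3), rng=rng).layers,
                    *_conv_relu(192, 192, (7, 1), pad=(3, 0), rng=rng).layers,
                    *_conv_relu(192, 192, 3, stride=2, rng=rng).layers,
                ]
            ),
            MaxPool2d(3, 2),
        ]
    )


def _inception_c(cin, rng) -> Branches:
    def split_3(cin_):
        return Branches(
            [
                _conv_relu(cin_, 384, (1, 3), pad=(0, 1), rng=rng),
                _conv_relu(cin_, 384, (3, 1), pad=(1, 0), rng=rng),
            ]
        )

    return Branches(
        [
            _conv_relu(cin, 320, 1, rng=rng),
            Sequential([*_conv_relu(cin, 384, 1, rng=rng).layers, split_3(384)]),
            Sequential(
                [
                    *_conv_relu(cin, 448, 1, rng=rng).layers,
                    *_conv_relu(448, 384, 3, pad=1, rng=rng).layers,
                    split_3(384),
                ]
            ),
            Sequential([AvgPool2d(3, 1, 1), *_conv_relu(cin, 192, 1, rng=rng).layers]),
        ]
    )


def build_inception_v3(input_side: int, rng: np.random.Generator) -> Network:
    """Standard Inception-V3 topology (11 inception modules) with a 2-way GAP head.

    Batch normalization is folded away (plain conv + ReLU): at 2-class desk
    scale the topology — stem, 3×A, reduction-A, 4×B, reduction-B, 2×C — is
    what matters, and the GAP head keeps CAM well-defined.
    """
    if input_side < 75:
        raise ValueError("inception_v3 needs input_side >= 75")
    stem = [
        Conv2d(3, 32, 3, stride=2, rng=rng),
        ReLU(),
        Conv2d(32, 32, 3, rng=rng),
        ReLU(),
        Conv2d(32, 64, 3, pad=1, rng=rng),
        ReLU(),
        MaxPool2d(3, 2),
        Conv2d(64, 80, 1, rng=rng),
        ReLU(),
        Conv2d(80, 192, 3, rng=rng),
        ReLU(),
        MaxPool2d(3, 2),
    ]
    modules = [
        _inception_a(192, 32, rng),   # -> 256
        _inception_a(256, 64, rng),   # -> 288
        _inception_a(288, 64, rng),   # -> 288
        _reduction_a(288, rng),       # -> 768
        _inception_b(768, 128, rng),
        _inception_b(768, 160, rng),
        _inception_b(768, 160, rng),
        _inception_b(768, 192, rng),
        _reduction_b(768, rng),       # -> 1280
        _inception_c(1280, rng),      # -> 2048
        _inception_c(2048, rng),
    ]
    features = Sequential(stem + modules)
    head = Linear(2048, 2, rng=rng)
    return Network(features, head, input_side, "inception_v3")
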