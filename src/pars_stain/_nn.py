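"""Minimal CPU convolutional-network engine for the multi-channel cycleGAN.

A compact, self-contained numpy implementation of exactly the pieces the
colorization model needs: stride-2 kernel-4 convolutions and transposed
convolutions, instance normalization, the usual activations, Adam, and
least-squares GAN / L1 losses.  Layers are purely functional with explicit
tapes — ``forward`` returns ``(y, cache)`` and ``backward(cache, dy)``
returns the input gradient while accumulating parameter gradients — so a
network can appear several times in one objective (cycle consistency needs
G∘F and F∘G) without cache clobbering.

Arrays are (batch, channels, height, width), float64.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2d",
    "InstanceNorm2d",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Sequential",
    "UNetGenerator",
    "PatchDiscriminator",
    "Adam",
    "lsgan_loss",
    "l1_loss",
    "ImageBuffer",
]

INIT_STD = 0.02  # DCGAN-style normal init


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x):  # -> (y, cache)
        raise NotImplementedError

    def backward(self, cache, dy, accumulate: bool = True):
        raise NotImplementedError


def _windows(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    """(B, C, Ho, Wo, k, k) sliding windows of a padded input."""
    w = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return w[:, :, ::s, ::s]


class Conv2d(Layer):
    def __init__(self, cin, cout, rng, k=4, stride=2, pad=1, bias=True):
        self.k, self.stride, self.pad = k, stride, pad
        self.W = Param(rng.normal(0.0, INIT_STD, (cout, cin, k, k)))
        self.b = Param(np.zeros(cout)) if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = _windows(xp, self.k, self.stride)
        y = np.einsum("bchwij,ocij->bohw", win, self.W.value, optimize=True)
        if self.b is not None:
            y += self.b.value[None, :, None, None]
        return y, (xp, x.shape)

    def backward(self, cache, dy, accumulate=True):
        xp, x_shape = cache
        k, s, p = self.k, self.stride, self.pad
        Ho, Wo = dy.shape[2], dy.shape[3]
        if accumulate:
            win = _windows(xp, k, s)
            self.W.grad += np.einsum("bohw,bchwij->ocij", dy, win, optimize=True)
            if self.b is not None:
                self.b.grad += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for i, j in product(range(k), range(k)):
            dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += np.einsum(
                "bohw,oc->bchw", dy, self.W.value[:, :, i, j], optimize=True
            )
        H, W = x_shape[2], x_shape[3]
        return dxp[:, :, p : p + H, p : p + W]


class ConvTranspose2d(Layer):
    """Adjoint of a stride-``s`` convolution; doubles spatial size for
    k=4, stride=2, pad=1."""

    def __init__(self, cin, cout, rng, k=4, stride=2, pad=1, bias=True):
        self.k, self.stride, self.pad = k, stride, pad
        # W maps cout -> cin under the paired forward convolution
        self.W = Param(rng.normal(0.0, INIT_STD, (cin, cout, k, k)))
        self.b = Param(np.zeros(cout)) if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def out_size(self, h: int) -> int:
        return (h - 1) * self.stride - 2 * self.pad + self.k

    def forward(self, x):
        B, C, H, W = x.shape
        k, s, p = self.k, self.stride, self.pad
        Hy, Wy = self.out_size(H), self.out_size(W)
        yp = np.zeros((B, self.W.value.shape[1], Hy + 2 * p, Wy + 2 * p))
        for i, j in product(range(k), range(k)):
            yp[:, :, i : i + s * H : s, j : j + s * W : s] += np.einsum(
                "bchw,co->bohw", x, self.W.value[:, :, i, j], optimize=True
            )
        y = yp[:, :, p : p + Hy, p : p + Wy]
        if self.b is not None:
            y += self.b.value[None, :, None, None]
        return y, (x, (Hy, Wy))

    def backward(self, cache, dy, accumulate=True):
        x, _ = cache
        k, s, p = self.k, self.stride, self.pad
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p)))
        win = _windows(dyp, k, s)  # (B, O, H, W, k, k) aligned with x
        if accumulate:
            self.W.grad += np.einsum("bchw,bohwij->coij", x, win, optimize=True)
            if self.b is not None:
                self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("bohwij,coij->bchw", win, self.W.value, optimize=True)
        return dx


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization over the spatial axes
    (no learned affine, matching the reference GAN convention)."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = np.mean(xc * xc, axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        y = xc * inv
        return y, (y, inv)

    def backward(self, cache, dy, accumulate=True):
        y, inv = cache
        m1 = dy.mean(axis=(2, 3), keepdims=True)
        m2 = (dy * y).mean(axis=(2, 3), keepdims=True)
        return inv * (dy - m1 - y * m2)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, cache, dy, accumulate=True):
        return np.where(cache, dy, self.slope * dy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, cache, dy, accumulate=True):
        return dy * (1.0 - cache * cache)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        tape = []
        for l in self.layers:
            x, c = l.forward(x)
            tape.append(c)
        return x, tape

    def backward(self, tape, dy, accumulate=True):
        for l, c in zip(reversed(self.layers), reversed(tape)):
            dy = l.backward(c, dy, accumulate)
        return dy


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


class UNetGenerator(Layer):
    """Encoder–decoder with skip connections.

    ``depth`` stride-2 kernel-4 downsampling convolutions (instance norm on
    all but the first, LeakyReLU 0.2), mirrored by transposed convolutions
    (instance norm + ReLU); each decoder level is concatenated with the
    matching encoder activation; the head is a transposed convolution to
    ``cout`` channels followed by tanh.  Requires input sides divisible by
    ``2**depth``.
    """

    def __init__(self, cin, cout, depth, ngf, rng, max_mult=8):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.depth = depth
        chs = [min(ngf * 2**i, ngf * max_mult) for i in range(depth)]
        self.chs = chs
        self.enc: list[Sequential] = []
        c_prev = cin
        for i in range(depth):
            block = [Conv2d(c_prev, chs[i], rng)]
            if i > 0:
                block.append(InstanceNorm2d())
            block.append(LeakyReLU(0.2))
            self.enc.append(Sequential(*block))
            c_prev = chs[i]
        self.dec: list[Sequential] = []
        self.dec_levels = list(range(depth - 2, -1, -1))
        c_prev = chs[-1]
        for i in self.dec_levels:
            self.dec.append(
                Sequential(
                    ConvTranspose2d(c_prev, chs[i], rng), InstanceNorm2d(), ReLU()
                )
            )
            c_prev = 2 * chs[i]  # after skip concatenation
        self.head = Sequential(ConvTranspose2d(c_prev, cout, rng), Tanh())

    def params(self):
        ps = [p for b in self.enc for p in b.params()]
        ps += [p for b in self.dec for p in b.params()]
        ps += self.head.params()
        return ps

    def forward(self, x):
        side = min(x.shape[2], x.shape[3])
        if side % (2**self.depth) != 0:
            raise ValueError(
                f"input side {side} not divisible by 2**depth={2**self.depth}"
            )
        enc_tapes, skips = [], []
        h = x
        for block in self.enc:
            h, t = block.forward(h)
            enc_tapes.append(t)
            skips.append(h)
        dec_tapes = []
        for block, i in zip(self.dec, self.dec_levels):
            h, t = block.forward(h)
            dec_tapes.append(t)
            h = np.concatenate([h, skips[i]], axis=1)
        y, head_tape = self.head.forward(h)
        return y, (enc_tapes, dec_tapes, head_tape)

    def backward(self, cache, dy, accumulate=True):
        enc_tapes, dec_tapes, head_tape = cache
        d = self.head.backward(head_tape, dy, accumulate)
        dskips = [None] * self.depth
        for block, i, t in zip(
            reversed(self.dec), reversed(self.dec_levels), reversed(dec_tapes)
        ):
            c = self.chs[i]
            d_up, d_skip = d[:, :c], d[:, c:]
            dskips[i] = d_skip if dskips[i] is None else dskips[i] + d_skip
            d = block.backward(t, d_up, accumulate)
        for i in range(self.depth - 1, -1, -1):
            if dskips[i] is not None:
                d = d + dskips[i]
            d = self.enc[i].backward(enc_tapes[i], d, accumulate)
        return d


class PatchDiscriminator(Sequential):
    """Patch-wise real/fake classifier: ``n_layers`` stride-2 kernel-4
    convolutions (instance norm from the second on, LeakyReLU 0.2) and a
    final stride-1 kernel-4 convolution to a 1-channel score map."""

    def __init__(self, cin, ndf, n_layers, rng, max_mult=8):
        layers: list[Layer] = []
        c_prev = cin
        for i in range(n_layers):
            c = min(ndf * 2**i, ndf * max_mult)
            layers.append(Conv2d(c_prev, c, rng))
            if i > 0:
                layers.append(InstanceNorm2d())
            layers.append(LeakyReLU(0.2))
            c_prev = c
        layers.append(Conv2d(c_prev, 1, rng, stride=1))
        super().__init__(*layers)


# ---------------------------------------------------------------------------
# optimization and losses
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: list[Param], lr: float, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def lsgan_loss(pred: np.ndarray, target: float):
    """Least-squares GAN objective; returns (loss, dloss/dpred)."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, 2.0 * diff / diff.size


def l1_loss(a: np.ndarray, b: np.ndarray):
    """Mean absolute error; returns (loss, dloss/da)."""
    diff = a - b
    loss = float(np.mean(np.abs(diff)))
    return loss, np.sign(diff) / diff.size


class ImageBuffer:
    """Replay buffer of previously generated images for discriminator
    updates (history of 50, half the queries swap with a stored image)."""

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.items: list[np.ndarray] = []

    def query(self, img: np.ndarray) -> np.ndarray:
        if self.size <= 0:
            return img
        if len(self.items) < self.size:
            self.items.append(img.copy())
            return img
        if self.rng.random() < 0.5:
            i = int(self.rng.integers(self.size))
            out = self.items[i]
            self.items[i] = img.copy()
            return out
        return img
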