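"""Minimal reverse-mode neural-network layers on numpy arrays.

Implements exactly the pieces the unrolled reconstruction networks need —
2-D convolution with same padding, batch normalization, ReLU, and an Adam
optimizer — with explicit ``forward``/``backward`` methods.  Arrays are
``(N, C, H, W)`` float64.  Every layer's backward pass is checked against
finite differences in the test suite.

This is intentionally a small, fixed toolbox rather than a general autodiff
tape: the unrolled architectures used here are static graphs, so each model
owns its layers and runs the reverse sweep itself.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "BatchNorm2d", "ReLU", "Adam", "he_init"]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


def he_init(rng: np.random.Generator, cout: int, cin: int, k: int) -> np.ndarray:
    """Fan-in-scaled Gaussian init for a (cout, cin, k, k) conv kernel."""
    std = np.sqrt(2.0 / (cin * k * k))
    return rng.standard_normal((cout, cin, k, k)) * std


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H+k-1, W+k-1) padded input -> (N, H, W, C*k*k) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


class Conv2d:
    """Same-padding 2-D convolution (cross-correlation), bias optional."""

    def __init__(self, cin: int, cout: int, k: int = 3, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.W = Param(he_init(rng, cout, cin, k))
        self.b = Param(np.zeros(cout)) if bias else None

    @property
    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    @property
    def n_params(self) -> int:
        return self.W.value.size + (self.b.value.size if self.b is not None else 0)

    def forward(self, x: np.ndarray):
        k, p = self.k, self.k // 2
        N, C, H, Wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = _im2col(xp, k).reshape(N * H * Wd, C * k * k)
        Wm = self.W.value.reshape(self.cout, C * k * k)
        out = cols @ Wm.T
        if self.b is not None:
            out += self.b.value
        out = out.reshape(N, H, Wd, self.cout).transpose(0, 3, 1, 2)
        return out, (cols, x.shape)

    def backward(self, dout: np.ndarray, cache):
        cols, xshape = cache
        N, C, H, Wd = xshape
        k, p = self.k, self.k // 2
        dmat = dout.transpose(0, 2, 3, 1).reshape(N * H * Wd, self.cout)
        self.W.grad += (dmat.T @ cols).reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += dmat.sum(axis=0)
        Wm = self.W.value.reshape(self.cout, C * k * k)
        dcols = (dmat @ Wm).reshape(N, H, Wd, C, k, k)
        dxp = np.zeros((N, C, H + 2 * p, Wd + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + Wd] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + H, p:p + Wd]


class BatchNorm2d:
    """Per-channel batch normalization with running statistics.

    Training mode normalizes by batch statistics over (N, H, W) and updates
    the running estimates; eval mode uses the running estimates.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    @property
    def n_params(self) -> int:
        return self.gamma.value.size + self.beta.value.size

    def forward(self, x: np.ndarray, train: bool):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        return out, (xhat, inv, train, x.shape)

    def backward(self, dout: np.ndarray, cache):
        xhat, inv, train, xshape = cache
        g = self.gamma.value[None, :, None, None]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * g
        if not train:
            return dxhat * inv[None, :, None, None]
        N, C, H, W = xshape
        nel = N * H * W
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return inv[None, :, None, None] / nel * (nel * dxhat - s1 - xhat * s2)


class ReLU:
    params: list = []
    n_params = 0

    def forward(self, x: np.ndarray):
        mask = x > 0
        return x * mask, mask

    def backward(self, dout: np.ndarray, mask):
        return dout * mask


class Adam:
    """Adam optimizer over a flat list of Params."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
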