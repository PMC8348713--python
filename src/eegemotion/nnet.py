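"""Minimal NumPy neural-network layers with reverse-mode gradients.

Implements exactly what the multi-scale-kernel classifier needs: same-
padding 2-D convolution (computed in the frequency domain), batch
normalization, ReLU, a fully connected layer, softmax / sigmoid
cross-entropy losses and the Adam optimizer.  All parameters and
activations are float32; weights use variance-scaling (fan-in)
initialization from a seeded generator.

Layers follow a small protocol: ``forward(x, train)`` caches what the
matching ``backward(grad)`` needs; ``parameters()`` yields
:class:`Parameter` objects that an optimizer updates in place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError


@dataclass
class Parameter:
    """A trainable array and its gradient."""

    value: np.ndarray
    grad: np.ndarray | None = None
    name: str = ""

    def zero_grad(self) -> None:
        self.grad = None


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []


class Conv2d(Layer):
    """Same-padding 2-D convolution over (N, C, H, W), stride 1, with bias.

    Implemented in the frequency domain: the zero-padded input is
    transformed once per layer (rfft2), every output is a per-bin
    contraction over input channels, and the inverse transform is cropped
    back to the input's spatial size.  For the 18x18 maps this problem
    uses, that is substantially faster than im2col and exact up to float32
    rounding; 1x1 convolutions bypass the FFT and reduce to a channel
    matmul.  The backward pass uses the adjoint contractions (correlation
    and convolution swap roles).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 == 0:
            raise ValidationError(f"kernel size must be odd, got {kernel_size}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Parameter(w.astype(np.float32), name=f"conv{kernel_size}x{kernel_size}.weight")
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32), name=f"conv{kernel_size}x{kernel_size}.bias")
        self._cache: tuple | None = None

    def _fft_sizes(self, h: int, w: int) -> tuple[int, int]:
        import scipy.fft as sfft

        return sfft.next_fast_len(h + self.k - 1), sfft.next_fast_len(w + self.k - 1)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        import scipy.fft as sfft

        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValidationError(f"expected {self.in_channels} input channels, got {c}")
        if self.k == 1:
            out = np.einsum("nchw,oc->nohw", x, self.weight.value[:, :, 0, 0], optimize=True)
            self._cache = (x,) if train else None
            return out + self.bias.value[None, :, None, None]
        p = self.k // 2
        l1, l2 = self._fft_sizes(h, w)
        xf = sfft.rfft2(x, s=(l1, l2))
        kf = sfft.rfft2(self.weight.value, s=(l1, l2))
        yf = np.einsum("ncab,ocab->noab", xf, kf.conj(), optimize=True)
        y = sfft.irfft2(yf, s=(l1, l2))
        ri = (np.arange(h) - p) % l1
        ci = (np.arange(w) - p) % l2
        out = y[:, :, ri[:, None], ci[None, :]]
        self._cache = (xf, kf, (n, c, h, w), (l1, l2), (ri, ci)) if train else None
        return out + self.bias.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        import scipy.fft as sfft

        if self._cache is None:
            raise RuntimeError("backward before forward(train=True)")
        if self.k == 1:
            (x,) = self._cache
            self.weight.grad = np.einsum("nohw,nchw->oc", grad, x, optimize=True)[:, :, None, None]
            self.bias.grad = grad.sum(axis=(0, 2, 3))
            dx = np.einsum("nohw,oc->nchw", grad, self.weight.value[:, :, 0, 0], optimize=True)
            self._cache = None
            return dx
        xf, kf, (n, c, h, w), (l1, l2), (ri, ci) = self._cache
        g = np.zeros((n, self.out_channels, l1, l2), dtype=grad.dtype)
        g[:, :, ri[:, None], ci[None, :]] = grad
        gf = sfft.rfft2(g)
        dx = sfft.irfft2(np.einsum("noab,ocab->ncab", gf, kf, optimize=True), s=(l1, l2))[:, :, :h, :w]
        dwf = np.einsum("ncab,noab->ocab", xf, gf.conj(), optimize=True)
        self.weight.grad = sfft.irfft2(dwf, s=(l1, l2))[:, :, : self.k, : self.k]
        self.bias.grad = grad.sum(axis=(0, 2, 3))
        self._cache = None
        return np.ascontiguousarray(dx)

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_channels, dtype=np.float32), name="bn.gamma")
        self.beta = Parameter(np.zeros(n_channels, dtype=np.float32), name="bn.beta")
        self.running_mean = np.zeros(n_channels, dtype=np.float32)
        self.running_var = np.ones(n_channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward before forward(train=True)")
        xhat, inv_std = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad = (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad = grad.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = grad * g
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        self._cache = None
        return term * inv_std[None, :, None, None]

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0 if train else None
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Linear(Layer):
    """Fully connected layer on flattened (N, features) input."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            w = np.zeros((out_features, in_features))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / in_features), (out_features, in_features))
        self.weight = Parameter(w.astype(np.float32), name="fc.weight")
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32), name="fc.bias")

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad = grad.T @ self._x
        self.bias.grad = grad.sum(axis=0)
        self._x = None
        return grad @ self.weight.value

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]


class MultiScaleBlock(Layer):
    """Parallel convolutions of distinct kernel sizes fused by 1x1 convolution.

    Every branch maps the input to ``out_channels`` feature maps at
    unchanged spatial size; the branch outputs are concatenated along the
    channel axis and a 1x1 convolution reduces them back to
    ``out_channels``, followed by batch normalization and ReLU.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_sizes: Sequence[int],
        rng: np.random.Generator,
    ):
        sizes = sorted(set(int(k) for k in kernel_sizes))
        if not sizes:
            raise ValidationError("kernel_sizes must be non-empty")
        for k in sizes:
            if k % 2 == 0:
                raise ValidationError(f"kernel size must be odd, got {k}")
        self.kernel_sizes = tuple(sizes)
        self.out_channels = out_channels
        self.branches = [Conv2d(in_channels, out_channels, k, rng) for k in sizes]
        self.fuse = Conv2d(len(sizes) * out_channels, out_channels, 1, rng)
        self.bn = BatchNorm2d(out_channels)
        self.act = ReLU()

    def _branch_cat(self, x: np.ndarray, train: bool) -> np.ndarray:
        """All branch outputs, concatenated along channels.

        The branches share one input FFT: every branch's response is a
        per-bin channel contraction against the same transformed input, so
        the branch kernels are stacked and contracted in a single batched
        operation, then cropped per branch (each kernel size has its own
        same-padding offset).  Identical to running the branches one by
        one, up to float32 rounding.
        """
        import scipy.fft as sfft

        n, c, h, w = x.shape
        k_max = max(self.kernel_sizes)
        l1 = sfft.next_fast_len(h + k_max - 1)
        l2 = sfft.next_fast_len(w + k_max - 1)
        xf = sfft.rfft2(x, s=(l1, l2))
        kf = sfft.rfft2(
            np.concatenate(
                [
                    np.pad(b.weight.value, ((0, 0), (0, 0), (0, k_max - b.k), (0, k_max - b.k)))
                    for b in self.branches
                ]
            ),
            s=(l1, l2),
        )
        y = sfft.irfft2(np.einsum("ncab,ocab->noab", xf, kf.conj(), optimize=True), s=(l1, l2))
        crops = []
        out = np.empty((n, len(self.branches) * self.out_channels, h, w), dtype=y.dtype)
        for i, b in enumerate(self.branches):
            p = b.k // 2
            ri = (np.arange(h) - p) % l1
            ci = (np.arange(w) - p) % l2
            crops.append((ri, ci))
            sl = slice(i * self.out_channels, (i + 1) * self.out_channels)
            out[:, sl] = y[:, sl][:, :, ri[:, None], ci[None, :]]
            out[:, sl] += b.bias.value[None, :, None, None]
        self._cache = (xf, kf, (n, c, h, w), (l1, l2), crops) if train else None
        return out

    def _branch_cat_backward(self, grad: np.ndarray) -> np.ndarray:
        import scipy.fft as sfft

        xf, kf, (n, c, h, w), (l1, l2), crops = self._cache
        g = np.zeros((n, len(self.branches) * self.out_channels, l1, l2), dtype=grad.dtype)
        for i, (ri, ci) in enumerate(crops):
            sl = slice(i * self.out_channels, (i + 1) * self.out_channels)
            g[:, sl, ri[:, None], ci[None, :]] = grad[:, sl]
            self.branches[i].bias.grad = grad[:, sl].sum(axis=(0, 2, 3))
        gf = sfft.rfft2(g)
        dx = sfft.irfft2(
            np.einsum("noab,ocab->ncab", gf, kf, optimize=True), s=(l1, l2)
        )[:, :, :h, :w]
        dw = sfft.irfft2(
            np.einsum("ncab,noab->ocab", xf, gf.conj(), optimize=True), s=(l1, l2)
        )
        for i, b in enumerate(self.branches):
            sl = slice(i * self.out_channels, (i + 1) * self.out_channels)
            b.weight.grad = np.ascontiguousarray(dw[sl, :, : b.k, : b.k])
        self._cache = None
        return np.ascontiguousarray(dx)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not np.isfinite(x).all():
            raise ValidationError("non-finite activations entering block")
        cat = self._branch_cat(x, train)
        y = self.fuse.forward(cat, train)
        y = self.bn.forward(y, train)
        return self.act.forward(y, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.act.backward(grad)
        grad = self.bn.backward(grad)
        grad = self.fuse.backward(grad)
        return self._branch_cat_backward(grad)

    def parameters(self) -> list[Parameter]:
        params = []
        for b in self.branches:
            params.extend(b.parameters())
        params.extend(self.fuse.parameters())
        params.extend(self.bn.parameters())
        return params


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer labels under a softmax head.

    Returns (loss, dloss/dlogits).  With two classes this is the binary
    cross-entropy of the equivalent sigmoid on the logit difference.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.maximum(p[np.arange(n), labels], 1e-30)).mean())
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


def sigmoid_binary_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy for a single-logit head; labels in {0, 1}."""
    z = logits.astype(np.float64).ravel()
    y = labels.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = ((p - y) / z.size).astype(np.float32).reshape(logits.shape)
    return loss, grad


class Adam:
    """Adam optimizer over a list of :class:`Parameter`."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
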