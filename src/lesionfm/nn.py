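"""A compact numpy framework for small 3D convolutional networks.

Layers operate on arrays shaped ``(batch, channels, x, y, z)`` and implement
explicit forward/backward passes, which keeps every gradient auditable and
makes guided back-propagation (zeroing negative gradients at rectifiers) a
one-flag variation of the ordinary backward pass.  Single precision, single
thread, fully deterministic given the initialization RNG.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=np.float32)
        self.g = np.zeros_like(self.v)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> List[Param]:
        return []

    def state_arrays(self) -> List[np.ndarray]:
        """All arrays that define the layer (parameters + running stats)."""
        return [p.v for p in self.parameters()]


def _windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    w = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    return w[:, :, ::stride, ::stride, ::stride]


class Conv3d(Layer):
    def __init__(self, in_c: int, out_c: int, k: int = 3, stride: int = 1,
                 padding: Optional[int] = None, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        rng = np.random.default_rng(rng)
        if padding is None:
            padding = k // 2
        self.in_c, self.out_c, self.k, self.stride, self.padding = in_c, out_c, k, stride, padding
        std = math.sqrt(2.0 / (in_c * k ** 3))
        self.W = Param(rng.normal(0.0, std, size=(out_c, in_c, k, k, k)))
        self.b = Param(np.zeros(out_c)) if bias else None
        self._xp: Optional[np.ndarray] = None

    def forward(self, x, train=False):
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        self._xp = xp  # cached for backward (weight grads and input grads)
        self._in_shape = x.shape
        win = _windows(xp, self.k, self.stride)
        out = np.tensordot(win, self.W.v, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        out = np.moveaxis(out, -1, 1)
        if self.b is not None:
            out = out + self.b.v[None, :, None, None, None]
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, grad, guided=False):
        if self._xp is None:
            raise RuntimeError("backward requires a forward pass with train=True")
        xp, k, s = self._xp, self.k, self.stride
        win = _windows(xp, k, s)  # (B, C, Ox, Oy, Oz, k, k, k)
        # dW: sum over batch and output positions
        self.W.g += np.tensordot(grad, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        if self.b is not None:
            self.b.g += grad.sum(axis=(0, 2, 3, 4))
        # dx: distribute grad through every kernel offset
        gw = np.tensordot(grad, self.W.v, axes=([1], [0]))  # (B, Ox, Oy, Oz, C, k, k, k)
        gw = np.moveaxis(gw, 4, 1)  # (B, C, Ox, Oy, Oz, k, k, k)
        dxp = np.zeros_like(xp)
        Ox, Oy, Oz = grad.shape[2:]
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    dxp[:, :, a:a + s * Ox:s, b:b + s * Oy:s, c:c + s * Oz:s] += gw[..., a, b, c]
        p = self.padding
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        return dxp.astype(np.float32)

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad, guided=False):
        g = np.where(self._mask, grad, 0.0)
        if guided:
            g = np.where(g > 0, g, 0.0)  # stop the flow of negative gradients
        return g.astype(np.float32)


class BatchNorm3d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3, 4))
            var = x.var(axis=(0, 2, 3, 4))
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        self._cache = (xhat, inv, x.shape, train)
        return (self.gamma.v[None, :, None, None, None] * xhat
                + self.beta.v[None, :, None, None, None]).astype(np.float32)

    def backward(self, grad, guided=False):
        xhat, inv, shape, trained = self._cache
        self.gamma.g += (grad * xhat).sum(axis=(0, 2, 3, 4))
        self.beta.g += grad.sum(axis=(0, 2, 3, 4))
        gy = grad * self.gamma.v[None, :, None, None, None]
        if not trained:
            # eval mode: an affine map with fixed statistics
            return (gy * inv[None, :, None, None, None]).astype(np.float32)
        m = shape[0] * shape[2] * shape[3] * shape[4]
        sum_gy = gy.sum(axis=(0, 2, 3, 4), keepdims=True)
        sum_gy_xhat = (gy * xhat).sum(axis=(0, 2, 3, 4), keepdims=True)
        dx = inv[None, :, None, None, None] * (gy - sum_gy / m - xhat * sum_gy_xhat / m)
        return dx.astype(np.float32)

    def parameters(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return [self.gamma.v, self.beta.v, self.run_mean, self.run_var]


class MaxPool3d(Layer):
    def __init__(self, k: int = 3, stride: int = 2, padding: int = 1):
        self.k, self.stride, self.padding = k, stride, padding
        self._cache = None

    def forward(self, x, train=False):
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)), constant_values=-np.inf) if p else x
        win = _windows(xp, self.k, self.stride)
        B, C, Ox, Oy, Oz = win.shape[:5]
        flat = win.reshape(B, C, Ox, Oy, Oz, -1)
        am = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, am[..., None], axis=-1)[..., 0]
        self._cache = (am, xp.shape, x.shape, (Ox, Oy, Oz))
        return out.astype(np.float32)

    def backward(self, grad, guided=False):
        am, xp_shape, x_shape, (Ox, Oy, Oz) = self._cache
        B, C = x_shape[:2]
        ka, kb, kc = np.unravel_index(am, (self.k, self.k, self.k))
        bi, ci, oi, oj, ok = np.indices((B, C, Ox, Oy, Oz), sparse=False)
        xi = oi * self.stride + ka
        yj = oj * self.stride + kb
        zk = ok * self.stride + kc
        dxp = np.zeros(xp_shape, dtype=np.float32)
        np.add.at(dxp, (bi, ci, xi, yj, zk), grad)
        p = self.padding
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        return dxp

    def parameters(self):
        return []


class GlobalPool(Layer):
    """Global spatial pooling: average, max, or their concatenation."""

    def __init__(self, mode: str = "avgmax"):
        if mode not in ("avg", "max", "avgmax"):
            raise ValueError("mode must be avg, max or avgmax")
        self.mode = mode
        self._cache = None

    def forward(self, x, train=False):
        B, C = x.shape[:2]
        flat = x.reshape(B, C, -1)
        avg = flat.mean(axis=-1)
        am = flat.argmax(axis=-1)
        mx = np.take_along_axis(flat, am[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, am)
        if self.mode == "avg":
            return avg.astype(np.float32)
        if self.mode == "max":
            return mx.astype(np.float32)
        return np.concatenate([avg, mx], axis=1).astype(np.float32)

    def backward(self, grad, guided=False):
        shape, am = self._cache
        B, C = shape[:2]
        nvox = int(np.prod(shape[2:]))
        dflat = np.zeros((B, C, nvox), dtype=np.float32)
        if self.mode == "avg":
            g_avg, g_max = grad, None
        elif self.mode == "max":
            g_avg, g_max = None, grad
        else:
            g_avg, g_max = grad[:, :C], grad[:, C:]
        if g_avg is not None:
            dflat += g_avg[..., None] / nvox
        if g_max is not None:
            np.put_along_axis(
                dflat, am[..., None],
                np.take_along_axis(dflat, am[..., None], axis=-1) + g_max[..., None], axis=-1,
            )
        return dflat.reshape(shape)

    def out_dim(self, channels: int) -> int:
        return 2 * channels if self.mode == "avgmax" else channels


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: Optional[np.random.Generator] = None):
        rng = np.random.default_rng(rng)
        std = math.sqrt(2.0 / d_in)
        self.W = Param(rng.normal(0.0, std, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self._x = None

    def forward(self, x, train=False):
        self._x = x
        return (x @ self.W.v + self.b.v).astype(np.float32)

    def backward(self, grad, guided=False):
        self.W.g += self._x.T @ grad
        self.b.g += grad.sum(axis=0)
        return (grad @ self.W.v.T).astype(np.float32)

    def parameters(self):
        return [self.W, self.b]


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad, guided=False):
        for layer in reversed(self.layers):
            grad = layer.backward(grad, guided=guided)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def state_arrays(self):
        return [a for layer in self.layers for a in layer.state_arrays()]


class Bottleneck(Layer):
    """Residual bottleneck block (1x1 -> 3x3 -> 1x1 convs with a skip path)."""

    def __init__(self, in_c: int, mid_c: int, out_c: int, stride: int = 1,
                 rng: Optional[np.random.Generator] = None):
        rng = np.random.default_rng(rng)
        self.conv1 = Conv3d(in_c, mid_c, k=1, stride=1, padding=0, bias=False, rng=rng)
        self.bn1 = BatchNorm3d(mid_c)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(mid_c, mid_c, k=3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm3d(mid_c)
        self.relu2 = ReLU()
        self.conv3 = Conv3d(mid_c, out_c, k=1, stride=1, padding=0, bias=False, rng=rng)
        self.bn3 = BatchNorm3d(out_c)
        self.relu_out = ReLU()
        if stride != 1 or in_c != out_c:
            self.down: Optional[Sequential] = Sequential([
                Conv3d(in_c, out_c, k=1, stride=stride, padding=0, bias=False, rng=rng),
                BatchNorm3d(out_c),
            ])
        else:
            self.down = None

    def forward(self, x, train=False):
        main = self.relu2.forward(self.bn2.forward(
            self.conv2.forward(self.relu1.forward(self.bn1.forward(
                self.conv1.forward(x, train), train), train), train), train), train)
        main = self.bn3.forward(self.conv3.forward(main, train), train)
        skip = self.down.forward(x, train) if self.down is not None else x
        return self.relu_out.forward(main + skip, train)

    def backward(self, grad, guided=False):
        g = self.relu_out.backward(grad, guided=guided)
        g_main = self.bn3.backward(g, guided)
        g_main = self.conv3.backward(g_main, guided)
        g_main = self.relu2.backward(g_main, guided=guided)
        g_main = self.bn2.backward(g_main, guided)
        g_main = self.conv2.backward(g_main, guided)
        g_main = self.relu1.backward(g_main, guided=guided)
        g_main = self.bn1.backward(g_main, guided)
        g_main = self.conv1.backward(g_main, guided)
        g_skip = self.down.backward(g, guided) if self.down is not None else g
        return g_main + g_skip

    def parameters(self):
        parts = [self.conv1, self.bn1, self.conv2, self.bn2, self.conv3, self.bn3]
        params = [p for m in parts for p in m.parameters()]
        if self.down is not None:
            params += self.down.parameters()
        return params

    def state_arrays(self):
        parts = [self.conv1, self.bn1, self.conv2, self.bn2, self.conv3, self.bn3]
        arrs = [a for m in parts for a in m.state_arrays()]
        if self.down is not None:
            arrs += self.down.state_arrays()
        return arrs


# ---------------------------------------------------------------------------
# losses, optimizer, schedules


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


class SGD:
    """SGD with momentum, weight decay and optional layer-wise adaptive
    rate control (LARS-style trust ratio per parameter tensor)."""

    def __init__(self, params: Sequence[Param], lr: float = 0.1, momentum: float = 0.9,
                 weight_decay: float = 1e-6, lars: bool = False, trust_coeff: float = 0.005):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.lars, self.trust_coeff = lars, trust_coeff
        self._buf = [np.zeros_like(p.v) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.g[...] = 0.0

    def step(self, lr: Optional[float] = None) -> None:
        lr = self.lr if lr is None else lr
        for p, buf in zip(self.params, self._buf):
            g = p.g + self.weight_decay * p.v
            local_lr = lr
            if self.lars:
                wn = float(np.linalg.norm(p.v))
                gn = float(np.linalg.norm(g))
                if wn > 0 and gn > 0:
                    local_lr = lr * self.trust_coeff * wn / gn
            buf *= self.momentum
            buf += g
            p.v -= local_lr * buf


def warmup_cosine_lr(base_lr: float, step: int, total_steps: int, warmup_frac: float = 0.1) -> float:
    """Linear warmup followed by cosine decay to zero."""
    warmup = max(1, int(round(warmup_frac * total_steps)))
    if step < warmup:
        return base_lr * (step + 1) / warmup
    t = (step - warmup) / max(1, total_steps - warmup)
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * min(1.0, t)))


def step_decay_lr(base_lr: float, epoch: int, step_size: int, gamma: float = 0.1) -> float:
    return base_lr * (gamma ** (epoch // max(1, step_size)))


def l2_normalize(v: np.ndarray, axis: int = -1, eps: float = 1e-12) -> np.ndarray:
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n < eps):
        raise ValueError("zero-norm embedding cannot be normalized")
    return v / n


def l2_normalize_backward(v: np.ndarray, grad_z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Backward of z = v / ||v|| given dL/dz."""
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    z = v / n
    return (grad_z - (grad_z * z).sum(axis=axis, keepdims=True) * z) / n
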