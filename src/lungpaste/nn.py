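"""Minimal NumPy neural-network framework with manual backpropagation.

Provides exactly the layers needed for the pretext classifier: strided
convolution (im2col), batch normalization, ReLU, 2x2 max pooling, global
average pooling, dense layers, and residual blocks, plus an SGD optimizer
with momentum/weight decay and a cosine-annealing schedule with warm
restarts. Everything is float32 and fully deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "ResidualBlock",
    "SGD",
    "cosine_annealing_lr",
    "softmax",
    "log_softmax",
    "cross_entropy_with_grad",
]

_DT = np.float32


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=_DT)
        self.grad = np.zeros_like(self.value)


class Module:
    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def state_arrays(self) -> list[np.ndarray]:
        """All persistent arrays (parameters + buffers) in a stable order."""
        out: list[np.ndarray] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v.value)
            elif isinstance(v, Module):
                out.extend(v.state_arrays())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.state_arrays())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Module):
    """2-D convolution via im2col; weight layout (cout, cin * k * k)."""

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kernel * kernel
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, fan_in)))
        self.b = Param(np.zeros(cout))
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, kernel, stride, pad
        self._cache: tuple | None = None

    def _cols(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        # layout (N, C*k*k, Ho*Wo): every later reshape is a free view
        n, c = xp.shape[:2]
        s, k = self.stride, self.k
        cols = np.empty((n, c, k, k, ho, wo), dtype=_DT)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
        return cols.reshape(n, c * k * k, ho * wo)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = self._cols(xp, ho, wo)
        out = np.matmul(self.w.value, cols) + self.b.value[None, :, None]
        self._cache = (cols, x.shape, ho, wo)
        return out.reshape(n, self.cout, ho, wo)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        p, k, s = self.pad, self.k, self.stride
        gmat = gout.reshape(n, self.cout, ho * wo)
        self.w.grad += np.einsum("ncp,nkp->ck", gmat, cols, optimize=True)
        self.b.grad += gmat.sum(axis=(0, 2))
        gcols = np.matmul(self.w.value.T, gmat).reshape(n, c, k, k, ho, wo)
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_DT)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += gcols[:, :, i, j]
        return gxp[:, :, p : p + h, p : p + w] if p else gxp


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=_DT)
        self.running_var = np.ones(channels, dtype=_DT)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def state_arrays(self) -> list[np.ndarray]:
        return [self.gamma.value, self.beta.value, self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd) if train else None
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        g = gout * self.gamma.value[None, :, None, None]
        mg = g.mean(axis=(0, 2, 3), keepdims=True)
        mgx = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
        gx = (g - mg - xhat * mgx) * invstd[None, :, None, None]
        return gx.astype(_DT)


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class MaxPool2d(Module):
    """2x2 max pooling with stride 2; input spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._am = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        onehot = (np.arange(4) == self._am[..., None]).astype(_DT)
        g4 = onehot * gout[..., None]
        gx = g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(gx.reshape(n, c, h, w))


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(gout[:, :, None, None] / (h * w), self._shape).astype(_DT)


class Dense(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / din), (dout, din)))
        self.b = Param(np.zeros(dout))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.w.grad += gout.T @ self._x
        self.b.grad += gout.sum(axis=0)
        return gout @ self.w.value


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


class ResidualBlock(Module):
    """conv-bn-relu-conv-bn plus (projected) identity, ReLU after the sum."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator | None = None):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, pad=1, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, pad=1, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.relu_out = ReLU()
        self.projection: Sequential | None = None
        if cin != cout or stride != 1:
            self.projection = Sequential(
                Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng), BatchNorm2d(cout)
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        main = self.bn2.forward(
            self.conv2.forward(
                self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train),
                train,
            ),
            train,
        )
        short = self.projection.forward(x, train) if self.projection is not None else x
        return self.relu_out.forward(main + short, train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(gout)
        gmain = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(g))))
        )
        gshort = self.projection.backward(g) if self.projection is not None else g
        return gmain + gshort


class SGD:
    """SGD with momentum and (coupled) weight decay."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        for p, v in zip(self.params, self.velocity):
            g = p.grad + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= _DT(lr) * v


def cosine_annealing_lr(
    base_lr: float, epoch: int, total_epochs: int, cycle_len: int | None = None
) -> float:
    """Cosine annealing with warm restarts every ``cycle_len`` epochs.

    With ``cycle_len=None`` a single cycle spans all epochs.
    """
    cycle = total_epochs if cycle_len is None else cycle_len
    t = epoch % cycle
    return 0.5 * base_lr * (1.0 + np.cos(np.pi * t / cycle))


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(logits))


def cross_entropy_with_grad(
    logits: np.ndarray, labels: np.ndarray, grad_scale: float = 1.0
) -> tuple[float, np.ndarray]:
    """Summed cross entropy over the batch and its gradient w.r.t. logits.

    ``grad_scale`` multiplies both the returned loss and the gradient, so the
    caller controls the normalization (e.g. 1 / number of image pairs).
    """
    if not np.isfinite(logits).all():
        raise ValueError("non-finite logits")
    n = logits.shape[0]
    lsm = log_softmax(logits.astype(np.float64))
    loss = -lsm[np.arange(n), labels].sum() * grad_scale
    grad = np.exp(lsm)
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad * grad_scale).astype(_DT)
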