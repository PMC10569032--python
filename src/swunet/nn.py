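"""Neural-network layers and the Adam optimizer on top of :mod:`swunet.autodiff`."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated at two standard deviations."""
    x = rng.standard_normal(shape) * std
    return np.clip(x, -2.0 * std, 2.0 * std).astype(np.float32)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Module:
    """Lightweight module container with recursive parameter discovery."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = ad.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, rng, stride=1, padding=0, bias=True):
        super().__init__()
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(he_normal(rng, (c_out, c_in, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    """Stride-2 transposed 3x3 convolution that exactly doubles the spatial side.

    Implemented as zero insertion followed by an ordinary convolution with the
    spatially flipped kernel (asymmetric bottom/right padding supplies the
    output offset that makes (H) -> (2H)).
    """

    def __init__(self, c_in, c_out, rng, kernel=3, stride=2):
        super().__init__()
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(he_normal(rng, (c_in, c_out, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32))
        self.kernel, self.stride = kernel, stride

    def forward(self, x: Tensor) -> Tensor:
        k, s = self.kernel, self.stride
        up = ad.zero_upsample2d(x, s)  # (H-1)*s + 1
        # pad so that conv with kernel k yields exactly s*H
        lo = (k - 1) // 2
        hi = k - 1 - lo + (s - 1)
        up = ad.pad(up, ((0, 0), (0, 0), (lo, hi), (lo, hi)))
        w = ad.flip(self.weight, (2, 3)).transpose(1, 0, 2, 3)
        return ad.conv2d(up, w, self.bias, stride=1, padding=0)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Parameter(np.ones(d, dtype=np.float32))
        self.bias = Parameter(np.zeros(d, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * ad.power(var + self.eps, -0.5)
        return xhat * self.gain + self.bias


class FeedForward(Module):
    """Position-wise MLP: affine -> GELU -> affine, hidden width ``ratio * d``."""

    def __init__(self, d: int, rng, ratio: int = 4):
        super().__init__()
        self.fc1 = Linear(d, ratio * d, rng)
        self.fc2 = Linear(ratio * d, d, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(ad.gelu(self.fc1(x)))


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            mhat = m / (1.0 - b1 ** self.t)
            vhat = v / (1.0 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
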