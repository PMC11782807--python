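"""Neural-network building blocks on top of the autodiff core.

Layers hold their parameters as named :class:`~cinefuse._autodiff.Tensor`
objects; an :class:`Adam` optimizer updates them in place.  Initialisation is
He-style and fully determined by the NumPy generator passed in, so training
runs are reproducible bit-for-bit from a seed.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, im2col

__all__ = ["Module", "Linear", "Conv2d", "Adam", "avg_pool2d", "global_avg_pool"]


class Module:
    """Base class: recursive named-parameter collection."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                out[name] = value
            elif isinstance(value, Module):
                for sub, p in value.parameters().items():
                    out[f"{name}.{sub}"] = p
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters().values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(2.0 / d_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(d_in, d_out)).astype(np.float32), requires_grad=True
        )
        self.bias = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Normalise the last axis to zero mean / unit variance, then affine."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.gamma + self.beta


class Conv2d(Module):
    """2-D convolution via im2col; input (N, C, H, W)."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator):
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(c_in * k * k, c_out)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        cols, out_h, out_w = im2col(x, self.k, self.stride, self.pad)
        # (N, C*k*k, L) -> (N*L, C*k*k) @ (C*k*k, F) -> (N, F, out_h, out_w)
        flat = cols.transpose(0, 2, 1).reshape(-1, self.c_in * self.k * self.k)
        out = flat @ self.weight + self.bias
        return out.reshape(n, out_h * out_w, self.c_out).transpose(0, 2, 1).reshape(
            n, self.c_out, out_h, out_w
        )


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling; H and W must divide by k."""
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims {(h, w)} not divisible by pool factor {k}")
    return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))


def global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3))


class Adam:
    """Adam with L2 weight decay folded into the gradient (PyTorch convention)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 weight_decay: float = 1e-8, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.weight_decay = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
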