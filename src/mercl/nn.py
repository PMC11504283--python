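"""Neural-network building blocks on top of the tensor engine.

Conventions: sequences are (B, T, D) float64 arrays; modules hold
``Parameter`` leaves and expose ``parameters()`` for the optimizer;
``train()`` / ``eval()`` toggle dropout and the normalization statistics.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Parameter, Tensor

__all__ = ["Module", "Linear", "Dropout", "BatchNorm", "Adam"]


class Module:
    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    training: bool = True

    def checksum(self) -> float:
        """Order-stable scalar digest of all parameter values (freeze checks)."""
        return float(sum(np.sum(p.data * (i + 1)) for i, p in enumerate(self.parameters())))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (in_features + out_features))
        self.weight = Parameter(rng.normal(0.0, scale, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = Tensor.as_tensor(x) @ self.weight
        return y + self.bias if self.bias is not None else y


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class BatchNorm(Module):
    """Feature-wise normalization over batch and time axes.

    In training mode statistics are taken over all axes except the last and
    running estimates are updated; in eval mode the running estimates are
    used, making the module deterministic and causal.  ``mode="layer"`` is a
    per-sample fallback for very small batches: each row is normalized over
    its feature axis with no batch statistics at all.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 mode: str = "batch"):
        if mode not in ("batch", "layer"):
            raise ValueError(f"unknown normalization mode {mode!r}")
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.momentum = momentum
        self.eps = eps
        self.mode = mode
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        x = Tensor.as_tensor(x)
        if self.mode == "layer":
            mu = x.mean(axis=-1, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
            xhat = (x - mu) / (var + self.eps).sqrt()
            return xhat * self.gamma + self.beta
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of Parameters."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
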