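"""Layers and optimization on top of :mod:`mvtomo.autodiff`.

The Module system is intentionally small: parameters and submodules are
auto-registered by attribute assignment, ``state_dict`` flattens them to
dotted names (numpy arrays, so checkpoints are plain ``.npz`` files), and
``train``/``eval`` toggles batch-norm statistics.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Parameter", "Linear", "Conv3d", "BatchNorm3d", "LayerNorm",
           "Sequential", "Adam"]


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_mods", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._mods[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self._mods[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._mods.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, mod in self._mods.items():
            yield from mod.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for mod in self._mods.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        out = {"param." + k: p.data.copy() for k, p in self.named_parameters()}
        out.update({"buffer." + k: b.copy() for k, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        expected = {"param." + k for k in params}
        buffers = {}
        for name, mod in self._named_modules():
            for bname in mod._buffers:
                buffers[name + bname] = (mod, bname)
        expected |= {"buffer." + k for k in buffers}
        missing = expected - set(state)
        extra = set(state) - expected
        if missing or extra:
            raise ValueError(
                f"checkpoint/model mismatch: missing {sorted(missing)[:5]}, "
                f"unexpected {sorted(extra)[:5]}"
            )
        for key, arr in state.items():
            kind, name = key.split(".", 1)
            if kind == "param":
                target = params[name]
                if target.data.shape != arr.shape:
                    raise ValueError(
                        f"checkpoint/model mismatch for {name}: "
                        f"{arr.shape} vs {target.data.shape}"
                    )
                target.data = np.asarray(arr, dtype=np.float32)
            else:
                mod, bname = buffers[name]
                mod._buffers[bname] = np.asarray(arr, dtype=np.float32)

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, mod in self._mods.items():
            yield from mod._named_modules(prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, std: float = 0.02):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(rng.normal(0.0, std, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv3d(Module):
    """3D convolution, zero 'same' padding, optional stride/dilation."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size**3
        std = float(np.sqrt(2.0 / fan_in))  # He init for ReLU stacks
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels,
                                       kernel_size, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        y = ad.conv3d(x, self.weight, stride=self.stride, dilation=self.dilation)
        if self.bias is not None:
            y = y + self.bias.reshape(1, -1, 1, 1, 1)
        return y


class BatchNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self._buffers["running_mean"] = np.zeros(channels, dtype=np.float32)
        self._buffers["running_var"] = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu
            ).astype(np.float32)
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var
            ).astype(np.float32)
            return ad.normalize(x, self.gamma.reshape(1, -1, 1, 1, 1),
                                self.beta.reshape(1, -1, 1, 1, 1), axes, self.eps)
        shape = (1, -1, 1, 1, 1)
        mu = Tensor(self._buffers["running_mean"].reshape(shape))
        var = Tensor(self._buffers["running_var"].reshape(shape))
        xhat = (x - mu) / ad.sqrt(var + self.eps)
        return xhat * self.gamma.reshape(1, -1, 1, 1, 1) + self.beta.reshape(1, -1, 1, 1, 1)


class LayerNorm(Module):
    """Normalization over the trailing channel axis."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ad.normalize(x, self.gamma, self.beta, (-1,), self.eps)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Adam:
    """Adam optimizer over a fixed parameter list; ``lr`` is mutable so a
    schedule can adjust it between steps."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
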