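"""Layer abstractions over the autodiff engine.

Modules own named parameters (Tensors with ``requires_grad``) and optional
non-trainable buffers (plain arrays, e.g. batch-norm running statistics).
``state_dict`` flattens both into a ``{name: ndarray}`` mapping whose keys
are stable dotted paths, so checkpoints are a single ``np.savez`` archive.

Every layer takes an explicit ``numpy.random.Generator`` at construction;
there is no global RNG state anywhere in the package.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, conv_transpose2d, relu

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "LayerNorm",
    "Linear",
    "ConvBnRelu",
]

_DTYPE = np.float32


class Module:
    """Base class: parameter registry, train/eval mode, checkpointing."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def add_module(self, name: str, module: "Module"):
        self._modules[name] = module
        object.__setattr__(self, name, module)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- checkpointing ----------------------------------------------------

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v.data.copy() for k, v in self._params.items()}
        out.update({prefix + k: v.copy() for k, v in self._buffers.items()})
        for mname, m in self._modules.items():
            out.update(m.state_dict(prefix + mname + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for k, p in self._params.items():
            p.data = np.asarray(state[prefix + k]).copy()
        for k in list(self._buffers):
            arr = np.asarray(state[prefix + k]).copy()
            self._buffers[k] = arr
            object.__setattr__(self, k, arr)
        for mname, m in self._modules.items():
            m.load_state_dict(state, prefix + mname + ".")

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as npz:
            self.load_state_dict({k: npz[k] for k in npz.files})

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape).astype(_DTYPE), requires_grad=True)


class Conv2d(Module):
    """2-D correlation layer; ``padding='same'`` keeps the spatial size."""

    def __init__(self, rng, in_ch: int, out_ch: int, kernel, stride: int = 1,
                 padding="same", groups: int = 1, bias: bool = True):
        super().__init__()
        if isinstance(kernel, int):
            kernel = (kernel, kernel)
        kh, kw = kernel
        if padding == "same":
            if stride != 1 and (kh % 2 == 0 or kw % 2 == 0):
                raise ValueError("'same' padding needs odd kernels")
            padding = (kh // 2, kw // 2)
        elif isinstance(padding, int):
            padding = (padding, padding)
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_ch // groups) * kh * kw
        self.weight = _he_init(rng, (out_ch, in_ch // groups, kh, kw), fan_in)
        self.bias = (
            Tensor(np.zeros(out_ch, dtype=_DTYPE), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups)


class ConvTranspose2d(Module):
    """Stride-s transposed convolution with kernel = stride (exact upsample)."""

    def __init__(self, rng, in_ch: int, out_ch: int, stride: int = 2, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.weight = _he_init(rng, (in_ch, out_ch, stride, stride), in_ch)
        self.bias = (
            Tensor(np.zeros(out_ch, dtype=_DTYPE), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    """Per-channel normalization; batch stats in training, running in eval."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(channels, dtype=_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=_DTYPE), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels, dtype=_DTYPE))
        self.register_buffer("running_var", np.ones(channels, dtype=_DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mean
            var = (centred * centred).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = rm = (
                (1 - m) * self._buffers["running_mean"] + m * mean.data.ravel()
            ).astype(_DTYPE)
            self._buffers["running_var"] = rv = (
                (1 - m) * self._buffers["running_var"] + m * var.data.ravel()
            ).astype(_DTYPE)
            object.__setattr__(self, "running_mean", rm)
            object.__setattr__(self, "running_var", rv)
            xhat = centred * (var + self.eps) ** -0.5
        else:
            mean = self._buffers["running_mean"][None, :, None, None]
            var = self._buffers["running_var"][None, :, None, None]
            xhat = (x - Tensor(mean)) * Tensor((var + self.eps) ** -0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class LayerNorm(Module):
    """Normalization over the last axis (token embeddings)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=_DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        centred = x - mean
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return centred * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Linear(Module):
    def __init__(self, rng, in_dim: int, out_dim: int, bias: bool = True):
        super().__init__()
        self.weight = _he_init(rng, (in_dim, out_dim), in_dim)
        self.bias = (
            Tensor(np.zeros(out_dim, dtype=_DTYPE), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class ConvBnRelu(Module):
    """The ubiquitous conv3x3 -> batch-norm -> ReLU unit."""

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1):
        super().__init__()
        self.conv = Conv2d(rng, in_ch, out_ch, kernel, stride=stride,
                           padding=(kernel // 2, kernel // 2))
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.conv(x)))
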