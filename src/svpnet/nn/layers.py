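"""Layer/module abstractions over the autograd tensor engine."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: parameter registry, train/eval mode, state dicts."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, ModuleList):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._buffers.items()}
        for name, m in self._modules.items():
            out.update(m.named_buffers(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters().items()}
        for k, v in self.named_buffers().items():
            state["buffer." + k] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        for k, p in params.items():
            if k not in state:
                raise KeyError(f"missing parameter {k!r} in state dict")
            if state[k].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()
        # buffers are located by walking the module tree
        for k, buf in self.named_buffers().items():
            key = "buffer." + k
            if key in state:
                self._set_buffer_by_path(k, np.asarray(state[key], dtype=np.float64))

    def _set_buffer_by_path(self, path: str, value: np.ndarray) -> None:
        parts = path.split(".")
        mod: Module = self
        for p in parts[:-1]:
            mod = mod._modules[p]
        mod._buffers[parts[-1]] = value
        object.__setattr__(mod, parts[-1], value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    """He-normal initialised weight in the engine's current default dtype."""
    w = rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)
    return Tensor(w.astype(T.get_default_dtype()), requires_grad=True)


def _zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape, dtype=T.get_default_dtype()), requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = _param(rng, (cout, cin, k, k), cin * k * k)
        self.bias = _zeros((cout,)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias)


class DepthwiseSeparableConv2d(Module):
    """Per-channel spatial convolution followed by a 1x1 pointwise mix."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.depthwise = _param(rng, (cin, k, k), k * k)
        self.pointwise = _param(rng, (cout, cin, 1, 1), cin)
        self.bias = _zeros((cout,)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = T.depthwise_conv2d(x, self.depthwise)
        return T.conv2d(y, self.pointwise, self.bias)

    def n_params(self) -> int:
        n = self.depthwise.data.size + self.pointwise.data.size
        if self.bias is not None:
            n += self.bias.data.size
        return n


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, k, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        if isinstance(k, int):
            k = (k, k, k)
        self.weight = _param(rng, (cout, cin) + tuple(k), cin * int(np.prod(k)))
        self.bias = _zeros((cout,)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv3d(x, self.weight, self.bias)


class Dense(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _param(rng, (nin, nout), nin)
        self.bias = _zeros((nout,))

    def forward(self, x: Tensor) -> Tensor:
        return T.matmul(x, self.weight) + self.bias


class BatchNorm(Module):
    """Batch normalisation over all axes except the channel axis.

    Works for (N,C,H,W) and (N,C,D,H,W) inputs with channel axis 1.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        dt = T.get_default_dtype()
        self.gamma = Tensor(np.ones(channels, dtype=dt), requires_grad=True)
        self.beta = _zeros((channels,))
        self.eps = eps
        self.momentum = momentum
        self._buffers["running_mean"] = np.zeros(channels, dtype=dt)
        self._buffers["running_var"] = np.ones(channels, dtype=dt)

    def forward(self, x: Tensor) -> Tensor:
        bshape = tuple(x.shape[1] if i == 1 else 1 for i in range(x.ndim))
        if self.training:
            out, mean, var = T.batch_norm_train(x, self.gamma, self.beta, self.eps)
            m, v = self.momentum, 1.0 - self.momentum
            self._buffers["running_mean"] = (
                m * self._buffers["running_mean"] + v * mean).astype(mean.dtype)
            self._buffers["running_var"] = (
                m * self._buffers["running_var"] + v * var).astype(var.dtype)
            return out
        rm = self._buffers["running_mean"].astype(x.data.dtype)
        rv = self._buffers["running_var"].astype(x.data.dtype)
        scale = self.gamma.data.reshape(-1) / np.sqrt(rv + self.eps)
        shift = -rm * scale
        xhat = T.mul(x, Tensor(scale.reshape(bshape))) + Tensor(shift.reshape(bshape))
        # gamma already folded into scale; only beta remains a live parameter
        return xhat + self.beta.reshape(bshape)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return T.dropout_mask(x, mask)


class LSTMCell(Module):
    """Standard dense LSTM cell (no peepholes) for flattened frame features."""

    def __init__(self, nin: int, nhidden: int, rng: np.random.Generator):
        super().__init__()
        self.nhidden = nhidden
        self.w_x = _param(rng, (nin, 4 * nhidden), nin)
        self.w_h = _param(rng, (nhidden, 4 * nhidden), nhidden)
        self.bias = _zeros((4 * nhidden,))

    def forward(self, x: Tensor, h: Tensor, c: Tensor):
        z = T.matmul(x, self.w_x) + T.matmul(h, self.w_h) + self.bias
        nh = self.nhidden
        i = T.sigmoid(z[:, 0 * nh:1 * nh])
        f = T.sigmoid(z[:, 1 * nh:2 * nh])
        g = T.tanh(z[:, 2 * nh:3 * nh])
        o = T.sigmoid(z[:, 3 * nh:4 * nh])
        c_new = T.mul(f, c) + T.mul(i, g)
        h_new = T.mul(o, T.tanh(c_new))
        return h_new, c_new
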