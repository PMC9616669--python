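"""Layer/module abstractions over the functional ops.

Modules hold named parameters and buffers, support train/eval switching and
flat ``state_dict`` serialization.  All random initialization draws from an
explicitly passed ``numpy.random.Generator`` so that network construction is
fully reproducible.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import DTYPE, Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in own:
                if own[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                own[name].data[...] = arr
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unexpected key {name}")
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"missing keys: {sorted(missing)}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 convolution with He-normal initialization."""

    def __init__(self, in_channels, out_channels, kernel_size=3, padding=1,
                 dilation=1, bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        std = np.sqrt(2.0 / (in_channels * k * k))
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels, k, k)))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None
        self.padding = padding
        self.dilation = dilation

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.padding, self.dilation)


class ConvTranspose2x2(Module):
    """Kernel-2 stride-2 transpose convolution (exact x2 upsampler)."""

    def __init__(self, in_channels, out_channels, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (in_channels * 4))
        self.weight = Parameter(rng.normal(0.0, std, (in_channels, out_channels, 2, 2)))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None

    def forward(self, x):
        return F.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(num_features, dtype=DTYPE))
        self.bias = Parameter(np.zeros(num_features, dtype=DTYPE))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(num_features, dtype=DTYPE))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return F.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE)) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self._layers = []
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)
            self._layers.append(layer)

    def forward(self, x):
        for layer in self._layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self._layers)


class ModuleList(Module):
    def __init__(self, items=()):
        super().__init__()
        self._items = []
        for item in items:
            self.append(item)

    def append(self, item):
        setattr(self, f"m{len(self._items)}", item)
        self._items.append(item)

    def __iter__(self):
        return iter(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def __len__(self):
        return len(self._items)


class Adam:
    """Adam with classic L2 weight decay folded into the gradient."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
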