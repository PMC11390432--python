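"""Trainable layers for the nested segmentation network.

A tiny ``Module`` system in the spirit of the mainstream deep-learning
frameworks: modules own named parameters (autograd leaf tensors) and
buffers (plain arrays such as batch-norm running statistics), can be
switched between train and eval mode, and can serialise their state to a
flat ``{name: array}`` dict for checkpointing.
"""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    batchnorm2d,
    conv2d,
    maxpool2x2,
    mul,
    relu,
    sigmoid,
    tmean,
    upsample_bilinear2x,
)

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ConvBlock", "SqueezeExcite"]


class Module:
    """Base class: parameter/buffer registry with recursive traversal."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        super().__setattr__(name, value)

    def register_parameter(self, name: str, value: Tensor):
        value.requires_grad = True
        self._params[name] = value
        setattr(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        setattr(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, mod in self._modules.items():
            yield from mod.named_buffers(prefix + mname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- checkpoint state ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=np.float32)
        for name, b in self.named_buffers():
            b[...] = state["buffer:" + name]

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Conv2d(Module):
    """Stride-1 'same' convolution with He-normal initialisation."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k = k
        self.pad = k // 2
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(cout, fan_in)).astype(np.float32)
        self.register_parameter("weight", Tensor(w))
        self.register_parameter("bias", Tensor(np.zeros(cout, dtype=np.float32)))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.k, self.pad)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.register_parameter("gamma", Tensor(np.ones(channels, dtype=np.float32)))
        self.register_parameter("beta", Tensor(np.zeros(channels, dtype=np.float32)))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float64))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float64))

    def __call__(self, x: Tensor) -> Tensor:
        return batchnorm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class SqueezeExcite(Module):
    """Channel attention: global average pool -> bottleneck MLP -> sigmoid gate."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 4):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Conv2d(channels, hidden, 1, rng)
        self.fc2 = Conv2d(hidden, channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        s = tmean(x, axis=(2, 3), keepdims=True)
        s = relu(self.fc1(s))
        s = sigmoid(self.fc2(s))
        return mul(x, s)


class ConvBlock(Module):
    """Node unit: two (conv3x3 -> norm -> ReLU) stages, optional channel attention."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, attention: bool):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.bn2 = BatchNorm2d(cout)
        self.se = SqueezeExcite(cout, rng) if attention else None

    def __call__(self, x: Tensor) -> Tensor:
        x = relu(self.bn1(self.conv1(x)))
        x = relu(self.bn2(self.conv2(x)))
        if self.se is not None:
            x = self.se(x)
        return x


# re-export the stateless ops layers commonly reach for
downsample = maxpool2x2
upsample = upsample_bilinear2x
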