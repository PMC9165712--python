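"""Layer modules and the Adam optimizer on top of the autodiff engine.

Conventions (documented because parameter-count and recovery tests depend
on them): convolution weights are He-uniform initialized over the fan-in,
biases start at zero, batch-norm scale/shift at one/zero.  Batch
normalization keeps per-channel running statistics with retention factor
``momentum`` (``running = momentum * running + (1 - momentum) * batch``,
default 0.9) and stabilizer ``eps`` (default 1e-5), switching between
batch and running statistics in train/eval mode.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

DTYPE = np.float32


def _key_str(key) -> str:
    if isinstance(key, tuple):
        return "_".join(str(part) for part in key)
    return str(key)


class Module:
    """Tiny module base: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def _children(self):
        """Yield (name, sub-object) for modules/parameters, flattening containers."""
        for name, v in vars(self).items():
            if isinstance(v, (Module, Parameter)):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, (Module, Parameter)):
                        yield f"{name}.{i}", item
            elif isinstance(v, dict):
                for k, item in v.items():
                    if isinstance(item, (Module, Parameter)):
                        yield f"{name}.{_key_str(k)}", item

    def modules(self):
        yield self
        for _, v in self._children():
            if isinstance(v, Module):
                yield from v.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self._children():
            if isinstance(v, Parameter):
                yield f"{prefix}{name}", v
            else:
                yield from v.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # ---- state (parameters + buffers such as batch-norm running stats) ----

    def named_buffer_slots(self, prefix: str = ""):
        """Yield (full name, owning module, attribute name) for every buffer."""
        for m_name, v in self._children():
            if isinstance(v, Module):
                yield from v.named_buffer_slots(f"{prefix}{m_name}.")
        for name in getattr(self, "_buffer_names", ()):
            yield f"{prefix}{name}", self, name

    def state_dict(self) -> dict:
        state = {f"param:{k}": p.data for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": getattr(owner, attr) for k, owner, attr in self.named_buffer_slots()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        slots = {k: (owner, attr) for k, owner, attr in self.named_buffer_slots()}
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unexpected parameter {name!r} in checkpoint")
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data = value.astype(params[name].data.dtype).copy()
            elif kind == "buffer":
                if name not in slots:
                    raise KeyError(f"unexpected buffer {name!r} in checkpoint")
                owner, attr = slots[name]
                setattr(owner, attr, value.copy())


def he_uniform(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv2d(Module):
    """Stride-1 'same' convolution with odd square kernel."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd to preserve spatial size")
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(he_uniform((out_channels, in_channels, kernel_size, kernel_size), fan_in, rng))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias)


class ConvTranspose2d2x2(Module):
    """2x2 stride-2 transposed convolution: doubles H and W."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(he_uniform((in_channels, out_channels, 2, 2), in_channels * 4, rng))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2d_2x2(x, self.weight, self.bias)


class UpsampleConv(Module):
    """Nearest-neighbour 2x upsampling followed by a 1x1 channel-reducing conv.

    Provided as the parameter-light alternative to the transposed-conv up edge.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(ad.upsample_nearest2x(x))


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        super().__init__()
        self.eps = float(eps)
        self.momentum = float(momentum)
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean = self.running_mean.astype(x.data.dtype)
            var = self.running_var.astype(x.data.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        inv = inv.astype(x.data.dtype)
        mean = mean.astype(x.data.dtype)
        xhat = (x.data - mean.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
        out = self.gamma.data.reshape(1, -1, 1, 1) * xhat + self.beta.data.reshape(1, -1, 1, 1)
        if not ad.grad_enabled():
            return Tensor(out)
        gamma, beta = self.gamma, self.beta
        training = self.training

        def backward(g):
            dgamma = (g * xhat).sum(axis=(0, 2, 3))
            dbeta = g.sum(axis=(0, 2, 3))
            gi = g * gamma.data.reshape(1, -1, 1, 1)
            if training:
                # backprop through the batch statistics
                mean_gi = gi.mean(axis=(0, 2, 3), keepdims=True)
                mean_gi_xhat = (gi * xhat).mean(axis=(0, 2, 3), keepdims=True)
                dx = inv.reshape(1, -1, 1, 1) * (gi - mean_gi - xhat * mean_gi_xhat)
            else:
                dx = gi * inv.reshape(1, -1, 1, 1)
            return dx, dgamma, dbeta

        return Tensor(out, parents=(x, gamma, beta), backward=backward)


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params, lr: float = 3e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data = (p.data.astype(np.float64) - update).astype(p.data.dtype)
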