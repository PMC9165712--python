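"""Recurrent and recurrent-residual convolution blocks.

The recurrent convolutional layer (RCL) unfolds a convolution over
``time_steps`` discrete steps: the first step is a plain feed-forward
convolution of the input, and each later step adds a recurrent
convolution of the previous step's output to the (shared) feed-forward
response before normalization and rectification,

    O_1 = relu(BN(w_f * x)),
    O_k = relu(BN(w_f * x + w_r_k * O_{k-1})),   k = 2..t.

The feed-forward kernel ``w_f`` is shared across steps; every recurrent
step owns a fresh kernel ``w_r_k``, so an RCL holds exactly ``t``
convolution weight sets.  A recurrent-residual layer (RRCL) stacks two
RCLs and adds the block input back on a shortcut, projected by a learned
1x1 convolution when the channel counts differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .nn import BatchNorm2d, Conv2d, Module


class ConfigurationError(ValueError):
    """Invalid block or network configuration."""


@dataclass(frozen=True)
class RCLConfig:
    in_channels: int
    out_channels: int
    time_steps: int = 2
    kernel_size: int = 3
    normalization: bool = True

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be positive")
        if self.time_steps < 1:
            raise ConfigurationError(f"time_steps must be >= 1, got {self.time_steps}")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ConfigurationError("kernel_size must be a positive odd integer")


@dataclass(frozen=True)
class RRCLConfig:
    rcl1: RCLConfig
    rcl2: RCLConfig = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.rcl2 is None:
            object.__setattr__(
                self,
                "rcl2",
                RCLConfig(
                    self.rcl1.out_channels,
                    self.rcl1.out_channels,
                    self.rcl1.time_steps,
                    self.rcl1.kernel_size,
                    self.rcl1.normalization,
                ),
            )
        if not (self.rcl1.out_channels == self.rcl2.in_channels == self.rcl2.out_channels):
            raise ConfigurationError("RRCL requires rcl1.out == rcl2.in == rcl2.out channels")

    @property
    def needs_projection(self) -> bool:
        return self.rcl1.in_channels != self.rcl2.out_channels


def conv_applications_per_rcl(t: int) -> int:
    """Distinct convolution weight sets held by one RCL unfolded to step t."""
    if t < 1:
        raise ConfigurationError(f"time step must be >= 1, got {t}")
    return t


class RCL(Module):
    """Recurrent convolutional layer (see module docstring for the unfolding)."""

    def __init__(self, cfg: RCLConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.feedforward = Conv2d(cfg.in_channels, cfg.out_channels, cfg.kernel_size, rng)
        self.recurrent = [
            Conv2d(cfg.out_channels, cfg.out_channels, cfg.kernel_size, rng)
            for _ in range(cfg.time_steps - 1)
        ]
        self.norms = [BatchNorm2d(cfg.out_channels) for _ in range(cfg.time_steps)] if cfg.normalization else []

    def _norm(self, k: int, x):
        return self.norms[k](x) if self.cfg.normalization else x

    def __call__(self, x):
        if x.data.shape[1] != self.cfg.in_channels:
            raise ConfigurationError(
                f"RCL configured for {self.cfg.in_channels} input channels, got {x.data.shape[1]}"
            )
        ff = self.feedforward(x)
        out = ad.relu(self._norm(0, ff))
        for k, conv_r in enumerate(self.recurrent, start=1):
            out = ad.relu(self._norm(k, ad.add(ff, conv_r(out))))
        return out


class RRCL(Module):
    """Two stacked RCLs with an additive (optionally projected) shortcut."""

    def __init__(self, cfg: RRCLConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.rcl1 = RCL(cfg.rcl1, rng)
        self.rcl2 = RCL(cfg.rcl2, rng)
        self.projection = Conv2d(cfg.rcl1.in_channels, cfg.rcl2.out_channels, 1, rng) if cfg.needs_projection else None

    def __call__(self, x):
        if x.data.shape[1] != self.cfg.rcl1.in_channels:
            raise ConfigurationError(
                f"RRCL configured for {self.cfg.rcl1.in_channels} input channels, got {x.data.shape[1]}"
            )
        shortcut = self.projection(x) if self.projection is not None else x
        return ad.add(shortcut, self.rcl2(self.rcl1(x)))


class PlainDoubleConv(Module):
    """Two conv+BN+ReLU stages — the vanilla U-Net / U-Net++ building block."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator, kernel_size: int = 3, normalization: bool = True):
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, kernel_size, rng)
        self.conv2 = Conv2d(out_channels, out_channels, kernel_size, rng)
        self.norms = [BatchNorm2d(out_channels), BatchNorm2d(out_channels)] if normalization else []
        self.normalization = normalization

    def __call__(self, x):
        h = self.conv1(x)
        h = ad.relu(self.norms[0](h) if self.normalization else h)
        h = self.conv2(h)
        return ad.relu(self.norms[1](h) if self.normalization else h)


def rcl_forward(x, cfg: RCLConfig, layer: RCL | None = None, rng: np.random.Generator | None = None):
    """Functional wrapper: run an RCL forward pass on an (N,C,H,W) array.

    Builds a fresh layer from ``rng`` when one is not supplied; tests use
    this to pin weights by hand before calling.
    """
    layer = layer if layer is not None else RCL(cfg, rng or np.random.default_rng(0))
    return layer(x if isinstance(x, ad.Tensor) else ad.Tensor(np.asarray(x)))


def rrcl_forward(x, cfg: RRCLConfig, layer: RRCL | None = None, rng: np.random.Generator | None = None):
    layer = layer if layer is not None else RRCL(cfg, rng or np.random.default_rng(0))
    return layer(x if isinstance(x, ad.Tensor) else ad.Tensor(np.asarray(x)))
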