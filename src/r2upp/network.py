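"""Nested dense-skip segmentation networks and their baselines.

The full model is a triangular graph of blocks X^(m,n) indexed by pyramid
level ``m`` (spatial size = input / 2^m) and skip-pathway column ``n``.
Column 0 is the encoder; block X^(m,n) with n > 0 convolves the channel
concatenation of every same-level predecessor X^(m,0..n-1) with the
up-sampled output of X^(m+1,n-1).  Down edges are 2x2/stride-2 max-pools,
up edges 2x2/stride-2 transposed convolutions that halve the channel
count (a nearest-neighbour-upsample + 1x1-conv alternative is available
via ``NetworkConfig.upsample``).  With deep supervision a 1x1 conv +
sigmoid head sits on every top-row node X^(0,q), q = 1..depth; the
embedded depth-q sub-model feeding head q can be extracted and run alone,
and averaging all heads gives the multi-depth ensemble prediction.

Four architectures share this machinery:

========  ==========  =======================  ==========
kind      topology    block                    heads
========  ==========  =======================  ==========
r2upp     nested      recurrent-residual       1 or depth
unetpp    nested      plain double conv        1 or depth
r2unet    straight    recurrent-residual       1
unet      straight    plain double conv        1
========  ==========  =======================  ==========
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import NamedTuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .blocks import ConfigurationError, PlainDoubleConv, RCLConfig, RRCL, RRCLConfig
from .nn import Conv2d, ConvTranspose2d2x2, Module, UpsampleConv


class NodeId(NamedTuple):
    m: int  # pyramid level, 0 = full resolution
    n: int  # skip-pathway column, 0 = encoder


@dataclass(frozen=True)
class NetworkConfig:
    depth: int = 4
    base_filters: tuple = (32, 64, 128, 256, 512)
    time_steps: int = 2
    deep_supervision: bool = True
    num_classes: int = 1
    input_channels: int = 1
    upsample: str = "transposed"  # or "upsample-conv"
    normalization: bool = True

    def __post_init__(self):
        object.__setattr__(self, "base_filters", tuple(int(f) for f in self.base_filters))
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if len(self.base_filters) != self.depth + 1:
            raise ConfigurationError(
                f"base_filters must list depth+1={self.depth + 1} channel counts, got {len(self.base_filters)}"
            )
        if self.num_classes < 1:
            raise ConfigurationError("num_classes must be >= 1")
        if self.upsample not in ("transposed", "upsample-conv"):
            raise ConfigurationError(f"unknown upsample mode {self.upsample!r}")


def _validate_node(node: NodeId, depth: int) -> None:
    if not (0 <= node.m <= depth and 0 <= node.n <= depth - node.m):
        raise ConfigurationError(f"node {tuple(node)} is outside the depth-{depth} triangular graph")


def node_inputs(node: NodeId, depth: int):
    """Ordered source descriptors feeding block X^(m,n).

    Returns tuples ``(kind, source)`` with kind in {"input", "down",
    "same", "up"}; concatenation order is same-level columns 0..n-1
    followed by the up-sampled input.
    """
    node = NodeId(*node)
    _validate_node(node, depth)
    m, n = node
    if n == 0:
        if m == 0:
            return [("input", None)]
        return [("down", NodeId(m - 1, 0))]
    sources = [("same", NodeId(m, k)) for k in range(n)]
    sources.append(("up", NodeId(m + 1, n - 1)))
    return sources


def skip_blocks_between(encoder: NodeId, decoder: NodeId) -> int:
    """Number of intermediate pathway blocks between X^(m,0) and X^(m,k)."""
    encoder, decoder = NodeId(*encoder), NodeId(*decoder)
    if encoder.m != decoder.m:
        raise ConfigurationError("encoder and decoder must sit on the same pyramid level")
    if encoder.n != 0:
        raise ConfigurationError("encoder node must be in column 0")
    if decoder.n < 1:
        raise ConfigurationError("decoder column must be >= 1")
    return decoder.n - 1


def _make_block(kind: str, in_ch: int, out_ch: int, cfg: NetworkConfig, rng) -> Module:
    if kind in ("r2upp", "r2unet"):
        rcl1 = RCLConfig(in_ch, out_ch, cfg.time_steps, normalization=cfg.normalization)
        return RRCL(RRCLConfig(rcl1), rng)
    return PlainDoubleConv(in_ch, out_ch, rng, normalization=cfg.normalization)


def _make_up(in_ch: int, out_ch: int, cfg: NetworkConfig, rng) -> Module:
    if cfg.upsample == "transposed":
        return ConvTranspose2d2x2(in_ch, out_ch, rng)
    return UpsampleConv(in_ch, out_ch, rng)


class SegmentationNetwork(Module):
    """Common surface: forward to per-head probability maps, prediction."""

    kind: str
    cfg: NetworkConfig

    def head_levels(self):
        raise NotImplementedError

    def forward(self, x) -> dict:
        raise NotImplementedError

    # -- helpers -----------------------------------------------------------

    def _as_batch(self, x) -> Tensor:
        if isinstance(x, Tensor):
            arr = x.data
        else:
            arr = np.asarray(x, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[:, None]
        if arr.ndim != 4:
            raise ConfigurationError("expected image input of shape HxW, NxHxW or NxCxHxW")
        if arr.shape[1] != self.cfg.input_channels:
            raise ConfigurationError(
                f"network expects {self.cfg.input_channels} input channel(s), got {arr.shape[1]}"
            )
        div = 2 ** self.cfg.depth
        h, w = arr.shape[2], arr.shape[3]
        if h % div or w % div:
            raise ConfigurationError(
                f"input spatial size {h}x{w} must be divisible by 2^depth = {div}"
            )
        return x if isinstance(x, Tensor) else Tensor(arr)

    def _head_activation(self, logits: Tensor) -> Tensor:
        if self.cfg.num_classes == 1:
            return ad.sigmoid(logits)
        return _softmax_channels(logits)

    def predict_proba(self, x) -> dict:
        """Eval-mode forward pass; returns {head level: (N,C,H,W) ndarray}."""
        was_training = self.training
        self.eval()
        try:
            with ad.no_grad():
                out = {q: t.data.copy() for q, t in self.forward(x).items()}
        finally:
            if was_training:
                self.train()
        return out


def _softmax_channels(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    if not ad.grad_enabled():
        return Tensor(p)

    def backward(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        return (p * (g - dot),)

    return Tensor(p, parents=(x,), backward=backward)


class NestedNetwork(SegmentationNetwork):
    """Triangular dense-skip graph (nested topology)."""

    def __init__(self, cfg: NetworkConfig, kind: str, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.kind = kind
        rng = np.random.default_rng(seed)
        f = cfg.base_filters
        self.nodes: dict = {}
        self.ups: dict = {}
        for m in range(cfg.depth + 1):
            for n in range(cfg.depth - m + 1):
                in_ch = cfg.input_channels if (m, n) == (0, 0) else (f[m - 1] if n == 0 else (n + 1) * f[m])
                self.nodes[NodeId(m, n)] = _make_block(kind, in_ch, f[m], cfg, rng)
                if n > 0:
                    self.ups[NodeId(m, n)] = _make_up(f[m + 1], f[m], cfg, rng)
        head_levels = list(range(1, cfg.depth + 1)) if cfg.deep_supervision else [cfg.depth]
        self.heads = {q: Conv2d(f[0], cfg.num_classes, 1, rng) for q in head_levels}

    def head_levels(self):
        return sorted(self.heads)

    def _run_graph(self, x: Tensor, max_col: int) -> dict:
        feats = {}
        for m in range(max_col + 1):
            src = x if m == 0 else ad.maxpool2x2(feats[NodeId(m - 1, 0)])
            feats[NodeId(m, 0)] = self.nodes[NodeId(m, 0)](src)
        for n in range(1, max_col + 1):
            for m in range(max_col - n + 1):
                up = self.ups[NodeId(m, n)](feats[NodeId(m + 1, n - 1)])
                cat = ad.concat_channels([feats[NodeId(m, k)] for k in range(n)] + [up])
                feats[NodeId(m, n)] = self.nodes[NodeId(m, n)](cat)
        return feats

    def forward(self, x) -> dict:
        x = self._as_batch(x)
        levels = self.head_levels()
        feats = self._run_graph(x, max(levels))
        return {q: self._head_activation(self.heads[q](feats[NodeId(0, q)])) for q in levels}


class StraightNetwork(SegmentationNetwork):
    """Plain U-shaped encoder-decoder with single skip concatenations."""

    def __init__(self, cfg: NetworkConfig, kind: str, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.kind = kind
        rng = np.random.default_rng(seed)
        f = cfg.base_filters
        self.encoders = [
            _make_block(kind, cfg.input_channels if m == 0 else f[m - 1], f[m], cfg, rng)
            for m in range(cfg.depth + 1)
        ]
        self.decoders = [
            _make_block(kind, 2 * f[m], f[m], cfg, rng) for m in range(cfg.depth - 1, -1, -1)
        ]
        self.ups = [_make_up(f[m + 1], f[m], cfg, rng) for m in range(cfg.depth - 1, -1, -1)]
        self.heads = {cfg.depth: Conv2d(f[0], cfg.num_classes, 1, rng)}

    def head_levels(self):
        return [self.cfg.depth]

    def forward(self, x) -> dict:
        x = self._as_batch(x)
        skips = []
        h = x
        for m, enc in enumerate(self.encoders):
            h = enc(h if m == 0 else ad.maxpool2x2(h))
            skips.append(h)
        for i, (up, dec) in enumerate(zip(self.ups, self.decoders)):
            m = self.cfg.depth - 1 - i
            h = dec(ad.concat_channels([skips[m], up(h)]))
        return {self.cfg.depth: self._head_activation(self.heads[self.cfg.depth](h))}


class PrunedNetwork(SegmentationNetwork):
    """Depth-q sub-model sharing every weight with its nested parent."""

    def __init__(self, parent: NestedNetwork, level: int):
        super().__init__()
        self.parent = parent
        self.level = level
        self.cfg = parent.cfg
        self.kind = f"{parent.kind}-L{level}"

    def head_levels(self):
        return [self.level]

    def forward(self, x) -> dict:
        x = self.parent._as_batch(x)
        feats = self.parent._run_graph(x, self.level)
        q = self.level
        return {q: self.parent._head_activation(self.parent.heads[q](feats[NodeId(0, q)]))}

    def train(self):
        self.parent.train()
        return self

    def eval(self):
        self.parent.eval()
        return self

    @property
    def training(self):
        return self.parent.training

    @training.setter
    def training(self, value):  # Module.__init__ assigns before parent exists
        if "parent" in vars(self):
            self.parent.training = value


ARCHITECTURES = ("unet", "r2unet", "unetpp", "r2upp")


def build_r2upp(cfg: NetworkConfig | None = None, seed: int = 0, **overrides) -> NestedNetwork:
    cfg = cfg if cfg is not None else NetworkConfig(**overrides)
    return NestedNetwork(cfg, "r2upp", seed)


def build_baseline(kind: str, cfg: NetworkConfig | None = None, seed: int = 0, **overrides) -> SegmentationNetwork:
    if kind not in ARCHITECTURES:
        raise ConfigurationError(f"unknown architecture {kind!r}; choose from {ARCHITECTURES}")
    cfg = cfg if cfg is not None else NetworkConfig(**overrides)
    if kind in ("unet", "r2unet"):
        return StraightNetwork(cfg, kind, seed)
    if kind == "unetpp":
        return NestedNetwork(cfg, "unetpp", seed)
    return NestedNetwork(cfg, "r2upp", seed)


def count_parameters(net: Module) -> int:
    """Exact count of trainable scalars (conv weights/biases, BN scale/shift, heads)."""
    return net.num_parameters()


def parameter_breakdown(net: SegmentationNetwork) -> list:
    """Per-component parameter counts: one row per block, up edge and head."""
    rows = []
    if isinstance(net, NestedNetwork):
        for node, block in sorted(net.nodes.items()):
            rows.append({"component": f"X({node.m},{node.n})", "params": block.num_parameters()})
        for node, up in sorted(net.ups.items()):
            rows.append({"component": f"up->X({node.m},{node.n})", "params": up.num_parameters()})
    elif isinstance(net, StraightNetwork):
        for m, enc in enumerate(net.encoders):
            rows.append({"component": f"enc({m})", "params": enc.num_parameters()})
        for i, dec in enumerate(net.decoders):
            rows.append({"component": f"dec({net.cfg.depth - 1 - i})", "params": dec.num_parameters()})
        for i, up in enumerate(net.ups):
            rows.append({"component": f"up({net.cfg.depth - 1 - i})", "params": up.num_parameters()})
    for q, head in sorted(net.heads.items()):
        rows.append({"component": f"head(L{q})", "params": head.num_parameters()})
    return rows


def params_in_millions(net: Module, sig_figs: int = 2) -> float:
    """Millions of parameters rounded the way architecture tables print them."""
    m = count_parameters(net) / 1e6
    if m == 0:
        return 0.0
    digits = sig_figs - 1 - int(np.floor(np.log10(abs(m))))
    return round(m, digits)


def extract_pruned(net: NestedNetwork, level: int) -> PrunedNetwork:
    """Weight-sharing depth-``level`` sub-model feeding head X^(0,level)."""
    if not isinstance(net, NestedNetwork):
        raise ConfigurationError("only nested networks embed prunable sub-models")
    if level not in net.heads:
        raise ConfigurationError(
            f"no supervised head at level {level}; available: {sorted(net.heads)}"
        )
    return PrunedNetwork(net, level)


def ensemble_predict(net: SegmentationNetwork, x) -> np.ndarray:
    """Arithmetic mean of all supervised head probability maps (eval mode)."""
    heads = net.predict_proba(x)
    return np.mean([heads[q] for q in sorted(heads)], axis=0)


# ---------------------------------------------------------------------------
# summary export and checkpointing
# ---------------------------------------------------------------------------


def summary_dict(net: SegmentationNetwork) -> dict:
    return {
        "kind": net.kind,
        "config": asdict(net.cfg),
        "total_params": count_parameters(net),
        "components": parameter_breakdown(net),
    }


def summary_text(net: SegmentationNetwork) -> str:
    d = summary_dict(net)
    width = max(len(r["component"]) for r in d["components"])
    lines = [f"{net.kind}  (total params: {d['total_params']:,})"]
    lines += [f"  {r['component']:<{width}}  {r['params']:>12,}" for r in d["components"]]
    return "\n".join(lines)


def save_checkpoint(net: SegmentationNetwork, path) -> None:
    if net.kind not in ARCHITECTURES:
        raise ConfigurationError(f"cannot checkpoint derived network kind {net.kind!r}")
    meta = json.dumps({"kind": net.kind, "config": asdict(net.cfg)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **net.state_dict())


def load_checkpoint(path) -> SegmentationNetwork:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = NetworkConfig(**{**meta["config"], "base_filters": tuple(meta["config"]["base_filters"])})
    net = build_baseline(meta["kind"], cfg)
    net.load_state_dict(state)
    return net
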