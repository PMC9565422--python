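"""Generator, discriminator (critic) and task-network architectures.

The translation network is a single conditional generator shared across all
domains: the target-domain code is one-hot encoded, tiled spatially and
concatenated to the input channels.  The critic is a PatchGAN that emits a
spatial map of real/fake scores plus a K-way domain-classification head.
Task networks are either a LeNet-style small CNN (default, digit scale) or a
pluggable feature backbone with a two-layer fully connected head.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .nn import Module, Tensor

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "TaskNetSpec", "one_hot",
    "Generator", "Discriminator", "SmallCNN", "DenseHeadNet",
    "build_generator", "build_discriminator", "build_task_net",
]


def one_hot(codes, k: int, dtype=np.float32) -> np.ndarray:
    codes = np.asarray(codes)
    if codes.ndim == 2:          # already one-hot
        return codes.astype(dtype)
    if codes.min() < 0 or codes.max() >= k:
        raise ValueError(f"domain code outside [0, {k})")
    out = np.zeros((len(codes), k), dtype=dtype)
    out[np.arange(len(codes)), codes] = 1.0
    return out


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class GeneratorSpec:
    image_size: int = 32
    in_channels: int = 3
    base_channels: int = 64
    n_down: int = 2              # stride-2 k4 p1 downsampling convolutions
    n_res: int = 4               # 4 at digit scale, 9 at radiograph scale
    n_domains: int = 2
    entry_kernel: int = 7        # odd kernel of the stride-1 entry/exit convs
    dtype: type = np.float32


@dataclass
class DiscriminatorSpec:
    image_size: int = 32
    in_channels: int = 3
    base_channels: int = 64
    n_conv: int = 6              # stride-2 k4 p1 conv layers
    leaky_slope: float = 0.01
    n_domains: int = 2
    auto_depth: bool = True      # shrink depth so the patch map stays >= 2x2
    dtype: type = np.float32


@dataclass
class TaskNetSpec:
    backbone: str = "small_cnn"  # or 'dense_head'
    n_classes: int = 10
    image_size: int = 32
    in_channels: int = 3
    hidden: tuple = (1000, 100)  # dense-head fully connected widths
    dropout: float = 0.5
    dtype: type = np.float32


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

class _ResBlock(Module):
    def __init__(self, ch, rng, dtype):
        super().__init__()
        self.c1 = nn.Conv2d(ch, ch, 3, 1, 1, rng=rng, dtype=dtype)
        self.n1 = nn.InstanceNorm2d(ch, dtype=dtype)
        self.c2 = nn.Conv2d(ch, ch, 3, 1, 1, rng=rng, dtype=dtype)
        self.n2 = nn.InstanceNorm2d(ch, dtype=dtype)

    def forward(self, x):
        h = nn.relu(self.n1(self.c1(x)))
        h = self.n2(self.c2(h))
        return x + h


class Generator(Module):
    """Conditional image-to-image translator G(x, c) with tanh output."""

    def __init__(self, spec: GeneratorSpec, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        down_factor = 2 ** spec.n_down
        min_size = 4 * down_factor
        if spec.image_size % down_factor or spec.image_size < min_size:
            raise ValueError(
                f"image size {spec.image_size} too small for {spec.n_down} "
                f"downsampling layers; minimum is {min_size} (and divisible by {down_factor})")
        dt = spec.dtype
        ch = spec.base_channels
        ek = spec.entry_kernel
        if ek % 2 == 0:
            raise ValueError("entry_kernel must be odd")
        mods = [nn.Conv2d(spec.in_channels + spec.n_domains, ch, ek, 1, ek // 2,
                          rng=rng, dtype=dt),
                nn.InstanceNorm2d(ch, dtype=dt), nn.ReLU()]
        for _ in range(spec.n_down):
            mods += [nn.Conv2d(ch, ch * 2, 4, 2, 1, rng=rng, dtype=dt),
                     nn.InstanceNorm2d(ch * 2, dtype=dt), nn.ReLU()]
            ch *= 2
        for _ in range(spec.n_res):
            mods.append(_ResBlock(ch, rng, dt))
        for _ in range(spec.n_down):
            mods += [nn.ConvTranspose2d(ch, ch // 2, 4, 2, 1, rng=rng, dtype=dt),
                     nn.InstanceNorm2d(ch // 2, dtype=dt), nn.ReLU()]
            ch //= 2
        mods += [nn.Conv2d(ch, spec.in_channels, ek, 1, ek // 2, rng=rng, dtype=dt),
                 nn.Tanh()]
        self.body = nn.Sequential(*mods)

    def forward(self, x, codes):
        """x: (B, C, H, W) tensor/array in [-1, 1]; codes: (B,) ints or (B, K) one-hot."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.spec.dtype))
        B, _, H, W = x.shape
        oh = one_hot(codes, self.spec.n_domains, self.spec.dtype)
        tiled = np.broadcast_to(oh[:, :, None, None], (B, self.spec.n_domains, H, W))
        xin = nn.concat([x, Tensor(np.ascontiguousarray(tiled))], axis=1)
        return self.body(xin)


# ---------------------------------------------------------------------------
# Discriminator / critic
# ---------------------------------------------------------------------------

def _conv_out(size: int, k: int = 4, s: int = 2, p: int = 1) -> int:
    return (size + 2 * p - k) // s + 1


class Discriminator(Module):
    """PatchGAN Wasserstein critic with a domain-classification head.

    No normalization layers: the critic must stay an unconstrained (and here
    piecewise-linear) function for the gradient penalty to behave.
    """

    def __init__(self, spec: DiscriminatorSpec, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        # feasible depth: final patch map must be at least 2x2
        size, feasible = spec.image_size, 0
        while _conv_out(size) >= 2:
            size = _conv_out(size)
            feasible += 1
        depth = spec.n_conv
        if depth > feasible:
            if not spec.auto_depth:
                raise ValueError(
                    f"{spec.n_conv} stride-2 layers infeasible at {spec.image_size}px; "
                    f"reduce n_conv to {feasible}")
            depth = feasible
        spec = replace(spec, n_conv=depth)
        self.spec = spec
        dt = spec.dtype
        ch_in, ch = spec.in_channels, spec.base_channels
        mods = []
        size = spec.image_size
        for _ in range(depth):
            mods += [nn.Conv2d(ch_in, ch, 4, 2, 1, rng=rng, dtype=dt),
                     nn.LeakyReLU(spec.leaky_slope)]
            size = _conv_out(size)
            ch_in, ch = ch, min(ch * 2, spec.base_channels * 8)
        self.features = nn.Sequential(*mods)
        self.map_size = size
        self.head_src = nn.Conv2d(ch_in, 1, 3, 1, 1, bias=False, rng=rng, dtype=dt)
        self.head_cls = nn.Conv2d(ch_in, spec.n_domains, size, 1, 0, bias=False,
                                  rng=rng, dtype=dt)

    def forward(self, x):
        """Returns (patch score map (B,1,M,M), domain logits (B,K))."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.spec.dtype))
        h = self.features(x)
        src = self.head_src(h)
        cls = self.head_cls(h).reshape(x.shape[0], self.spec.n_domains)
        return src, cls

    def src_scores(self, x) -> Tensor:
        """Per-item critic score: spatial mean of the patch map, shape (B,)."""
        src, _ = self.forward(x)
        return src.mean(axis=(1, 2, 3))


# ---------------------------------------------------------------------------
# Task networks
# ---------------------------------------------------------------------------

class SmallCNN(Module):
    """LeNet-style classifier: two conv+pool stages, three linear layers."""

    def __init__(self, spec: TaskNetSpec, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        dt = spec.dtype
        s1 = (spec.image_size - 4) // 2
        s2 = (s1 - 4) // 2
        if s2 < 2:
            raise ValueError(f"image size {spec.image_size} too small for the small CNN")
        self.n_features = 16 * s2 * s2
        self.body = nn.Sequential(
            nn.Conv2d(spec.in_channels, 6, 5, 1, 0, rng=rng, dtype=dt), nn.ReLU(),
            nn.AvgPool2d(2),
            nn.Conv2d(6, 16, 5, 1, 0, rng=rng, dtype=dt), nn.ReLU(),
            nn.AvgPool2d(2), nn.Flatten(),
            nn.Linear(self.n_features, 120, rng=rng, dtype=dt), nn.ReLU(),
            nn.Linear(120, 84, rng=rng, dtype=dt), nn.ReLU(),
            nn.Linear(84, spec.n_classes, rng=rng, dtype=dt),
        )

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.spec.dtype))
        return self.body(x)


class _DefaultBackbone(Module):
    """Small strided conv feature extractor used when no pretrained
    backbone is plugged in; emits a 64-d feature vector."""

    n_features = 64

    def __init__(self, in_channels, rng, dtype):
        super().__init__()
        self.body = nn.Sequential(
            nn.Conv2d(in_channels, 16, 3, 2, 1, rng=rng, dtype=dtype), nn.ReLU(),
            nn.Conv2d(16, 32, 3, 2, 1, rng=rng, dtype=dtype), nn.ReLU(),
            nn.Conv2d(32, 64, 3, 2, 1, rng=rng, dtype=dtype), nn.ReLU(),
        )

    def forward(self, x):
        h = self.body(x)
        return h.mean(axis=(2, 3))


class DenseHeadNet(Module):
    """Feature backbone + two fully connected layers (1000, 100 hidden nodes)
    with batch normalization, ReLU and 50% dropout, then a linear classifier."""

    def __init__(self, spec: TaskNetSpec, rng=None, backbone: Module | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        dt = spec.dtype
        self.backbone = backbone or _DefaultBackbone(spec.in_channels, rng, dt)
        h1, h2 = spec.hidden
        nf = self.backbone.n_features
        self.head = nn.Sequential(
            nn.Linear(nf, h1, rng=rng, dtype=dt), nn.BatchNorm1d(h1, dtype=dt),
            nn.ReLU(), nn.Dropout(spec.dropout, rng=rng),
            nn.Linear(h1, h2, rng=rng, dtype=dt), nn.BatchNorm1d(h2, dtype=dt),
            nn.ReLU(), nn.Dropout(spec.dropout, rng=rng),
            nn.Linear(h2, spec.n_classes, rng=rng, dtype=dt),
        )

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.spec.dtype))
        return self.head(self.backbone(x))


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_generator(spec: GeneratorSpec, rng=None) -> Generator:
    return Generator(spec, rng)


def build_discriminator(spec: DiscriminatorSpec, rng=None) -> Discriminator:
    return Discriminator(spec, rng)


def build_task_net(spec: TaskNetSpec, rng=None, backbone: Module | None = None) -> Module:
    if spec.backbone == "small_cnn":
        return SmallCNN(spec, rng)
    if spec.backbone == "dense_head":
        return DenseHeadNet(spec, rng, backbone)
    raise ValueError(f"unknown backbone {spec.backbone!r}")
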