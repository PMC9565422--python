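"""Synthetic multi-domain image benchmarks with controlled domain shift.

Two tasks emulate the structure of multi-site image classification:

* ``digitlike`` — ten procedurally rendered glyph classes (seven-segment
  style skeletons with random affine jitter) on 32x32 canvases, standing in
  for handwritten-digit corpora drawn from several style populations.
* ``opacitylike`` — binary detection of a soft-edged elliptical intensity
  elevation on a textured noise background, standing in for radiograph
  opacity screening.

A :class:`DomainStyle` is a label-independent transform of pixel statistics
(per-channel affine color map, gamma/contrast, background texture, additive
noise).  All domains share one class-generating process; only the style
differs, so class semantics are preserved across domains by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .data import LabeledImageSet, normalize

__all__ = [
    "DomainStyle", "TaskSpec", "make_domains", "render_glyph", "opacity_blob",
    "identity_style", "tint_style", "style_ladder", "no_shift_pair",
    "strong_shift_pair",
]

# Seven-segment-style skeletons in unit coordinates (x right, y down).
_L, _R, _T, _M, _B = 0.28, 0.72, 0.16, 0.50, 0.84
_SEG = {
    "top": (_L, _T, _R, _T), "mid": (_L + 0.04, _M, _R - 0.04, _M),
    "bot": (_L, _B, _R, _B), "lu": (_L, _T, _L, _M), "ll": (_L, _M, _L, _B),
    "ru": (_R, _T, _R, _M), "rl": (_R, _M, _R, _B),
}
_GLYPHS = {
    0: ["top", "bot", "lu", "ll", "ru", "rl"],
    1: [(0.50, _T, 0.50, _B), (0.38, 0.28, 0.50, _T)],
    2: ["top", "ru", "mid", "ll", "bot"],
    3: ["top", "ru", "mid", "rl", "bot"],
    4: ["lu", "mid", "ru", "rl"],
    5: ["top", "lu", "mid", "rl", "bot"],
    6: ["top", "lu", "ll", "mid", "rl", "bot"],
    7: ["top", (_R, _T, 0.42, _B)],
    8: ["top", "mid", "bot", "lu", "ll", "ru", "rl"],
    9: ["top", "lu", "mid", "ru", "rl", "bot"],
}


def _segments(cls: int) -> np.ndarray:
    return np.array([_SEG[s] if isinstance(s, str) else s for s in _GLYPHS[cls]],
                    dtype=np.float64)


def render_glyph(cls: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Render one jittered glyph as a (size, size) array in [0, 1]."""
    seg = _segments(cls).reshape(-1, 2, 2)  # (S, 2 endpoints, xy)
    ang = rng.normal(0.0, 0.10)
    sc = rng.uniform(0.85, 1.10, size=2)
    shift = rng.uniform(-0.06, 0.06, size=2)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    pts = (seg - 0.5) * sc @ rot.T + 0.5 + shift

    yy, xx = np.mgrid[0:size, 0:size]
    p = np.stack([(xx + 0.5) / size, (yy + 0.5) / size], axis=-1).reshape(-1, 2)
    a, b = pts[:, 0], pts[:, 1]                    # (S, 2)
    ab = b - a
    denom = (ab ** 2).sum(axis=1) + 1e-12
    ap = p[:, None, :] - a[None, :, :]             # (P, S, 2)
    t = np.clip((ap * ab[None]).sum(axis=2) / denom, 0.0, 1.0)
    closest = a[None] + t[..., None] * ab[None]
    d = np.sqrt(((p[:, None, :] - closest) ** 2).sum(axis=2)).min(axis=1)

    w = rng.uniform(0.045, 0.07)
    ink = rng.uniform(0.75, 0.95)
    img = ink * np.clip((w - d) / 0.03 + 0.5, 0.0, 1.0)
    return img.reshape(size, size)


def opacity_blob(canvas: np.ndarray, present: bool, rng: np.random.Generator,
                 amplitude: float = 0.35, radius_range=(0.10, 0.22),
                 return_mask: bool = False):
    """Add (or not) one soft-edged elliptical intensity elevation.

    The blob center is uniform over the region where the ellipse fits
    entirely inside the canvas.  With ``present=False`` the canvas is
    returned unchanged.
    """
    canvas = np.asarray(canvas, dtype=np.float64)
    if canvas.min() < 0 or canvas.max() > 1:
        raise ValueError("canvas values must lie in [0, 1]")
    if not present:
        return (canvas.copy(), np.zeros_like(canvas)) if return_mask else canvas.copy()
    h, w = canvas.shape
    ry = rng.uniform(*radius_range) * h
    rx = rng.uniform(*radius_range) * w
    if 2 * ry > h or 2 * rx > w:
        raise ValueError("blob size exceeds canvas")
    cy = rng.uniform(ry, h - ry)
    cx = rng.uniform(rx, w - rx)
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.sqrt(((yy + 0.5 - cy) / ry) ** 2 + ((xx + 0.5 - cx) / rx) ** 2)
    mask = np.clip((1.0 - r) / 0.3 + 0.5, 0.0, 1.0)  # soft edge near r = 1
    out = np.clip(canvas + amplitude * mask, 0.0, 1.0)
    return (out, mask) if return_mask else out


@dataclass
class DomainStyle:
    """Label-independent transform of pixel statistics; maps [0,1] into [0,1]."""

    name: str = "identity"
    channel_gain: tuple = (1.0, 1.0, 1.0)
    channel_offset: tuple = (0.0, 0.0, 0.0)
    gamma: float = 1.0
    noise_sigma: float = 0.0
    texture: float = 0.0

    def apply(self, images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Apply the style to (n, H, W, 3) images in [0, 1]."""
        x = np.asarray(images, dtype=np.float64)
        if x.min() < 0 or x.max() > 1:
            raise ValueError("style input must lie in [0, 1]")
        if self.gamma != 1.0:
            x = x ** self.gamma
        x = x * np.asarray(self.channel_gain) + np.asarray(self.channel_offset)
        if self.texture > 0:
            # soft low-frequency clutter, the photographic-background analogue
            tex = rng.standard_normal(x.shape[:3])
            tex = gaussian_filter(tex, sigma=(0, 2.5, 2.5))
            tex /= np.abs(tex).max() + 1e-12
            x = x + self.texture * tex[..., None]
        if self.noise_sigma > 0:
            x = x + rng.normal(0.0, self.noise_sigma, size=x.shape)
        return np.clip(x, 0.0, 1.0)


def identity_style(name: str = "identity") -> DomainStyle:
    return DomainStyle(name=name)


def tint_style(severity: float, name: str | None = None) -> DomainStyle:
    """A style ladder point: color tint with progressive polarity inversion
    of the green channel, contrast change, background texture and noise —
    the kind of shift separating grayscale digit corpora from colorized
    ones blended over photographic backgrounds.

    ``severity`` in [0, 1]; 0 is the identity, 1 is the strong-shift style.
    """
    s = float(severity)
    if not 0.0 <= s <= 1.0:
        raise ValueError("severity must be in [0, 1]")
    return DomainStyle(
        name=name or f"tint{s:.2f}",
        channel_gain=(1.0, 1.0 - 1.6 * s, 1.0 - 0.55 * s),
        channel_offset=(0.15 * s, 0.75 * s, 0.10 * s),
        gamma=1.0 + 1.4 * s,
        noise_sigma=0.10 * s,
        texture=0.20 * s,
    )


def style_ladder(severities=(0.0, 0.8, 1.0)) -> list[DomainStyle]:
    return [tint_style(s) for s in severities]


def no_shift_pair() -> list[DomainStyle]:
    return [identity_style("plain_a"), identity_style("plain_b")]


def strong_shift_pair() -> list[DomainStyle]:
    return [identity_style("gray"), tint_style(1.0, "strong_tint")]


@dataclass
class TaskSpec:
    """What to generate: the shared classification task and per-domain size."""

    task: str = "digitlike"            # 'digitlike' (N=10) or 'opacitylike' (N=2)
    n_per_domain: int = 2500           # 2000/250/250 after an 80/10/10 split
    image_size: int = 32
    prevalence: float = 0.5            # positive-class fraction (opacitylike)
    blob_amplitude: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("digitlike", "opacitylike"):
            raise ValueError("task must be 'digitlike' or 'opacitylike'")
        if self.n_per_domain < 1:
            raise ValueError("need at least one sample per domain")

    @property
    def n_classes(self) -> int:
        return 10 if self.task == "digitlike" else 2


def _base_images(spec: TaskSpec, labels: np.ndarray, rng) -> np.ndarray:
    s = spec.image_size
    out = np.empty((len(labels), s, s), dtype=np.float64)
    for i, y in enumerate(labels):
        if spec.task == "digitlike":
            out[i] = render_glyph(int(y), s, rng)
        else:
            canvas = 0.40 + 0.35 * gaussian_filter(rng.standard_normal((s, s)), 2.0)
            canvas = np.clip(canvas, 0.0, 1.0)
            out[i] = opacity_blob(canvas, bool(y), rng, amplitude=spec.blob_amplitude)
    return out


def make_domains(spec: TaskSpec, styles: list[DomainStyle]) -> list[LabeledImageSet]:
    """Generate one LabeledImageSet per style; deterministic for a fixed seed.

    The class-generating process is identical across domains (same code,
    independent draws); only the DomainStyle differs, so domain index is the
    only systematic difference between sets.
    """
    if len(styles) < 2:
        raise ValueError("adaptation needs at least 2 styles/domains")
    seeds = np.random.SeedSequence(spec.seed).spawn(len(styles))
    sets = []
    for d, (style, ss) in enumerate(zip(styles, seeds)):
        rng = np.random.default_rng(ss)
        if spec.task == "digitlike":
            labels = rng.integers(0, 10, spec.n_per_domain)
        else:
            labels = (rng.random(spec.n_per_domain) < spec.prevalence).astype(np.int64)
        base = _base_images(spec, labels, rng)
        rgb = np.repeat(base[..., None], 3, axis=3)
        styled = style.apply(rgb, rng)
        images = normalize(styled).astype(np.float32)
        man = pd.DataFrame({
            "path": [f"synthetic:{spec.task}/{style.name}/{i}" for i in range(len(labels))],
            "class": labels, "domain": d, "style": style.name,
        })
        sets.append(LabeledImageSet(images, labels, np.full(len(labels), d), man))
    return sets
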