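"""Multi-domain labeled image datasets: I/O, preprocessing, splits, batching.

On disk a dataset is a directory of PNG files plus a CSV manifest with
columns ``path,class,domain``.  In memory images are float arrays of shape
(n, H, W, C) normalized to [-1, 1]; class and domain labels are integer
vectors of the same length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "LabeledImageSet", "SplitSpec", "BatchPlan", "MixedBatch",
    "normalize", "denormalize", "load_dataset", "save_dataset",
    "split_dataset", "iterate_batches",
]

_INTERP = {"nearest": Image.NEAREST, "bilinear": Image.BILINEAR}


def normalize(raw: np.ndarray) -> np.ndarray:
    """Map pixel values from [0, 1] to [-1, 1]: (x - 0.5) / 0.5."""
    raw = np.asarray(raw)
    lo, hi = float(raw.min()), float(raw.max())
    if lo < 0.0 or hi > 1.0:
        raise ValueError(f"input values outside [0, 1]: range [{lo:.4g}, {hi:.4g}]")
    return (raw - 0.5) / 0.5


def denormalize(img: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize`: map [-1, 1] back to [0, 1]."""
    return np.asarray(img) * 0.5 + 0.5


@dataclass
class LabeledImageSet:
    """Images with per-item class and domain labels.

    ``images`` is (n, H, W, C) in [-1, 1]; ``manifest`` records the source
    path or generation parameters of each item.
    """

    images: np.ndarray
    class_labels: np.ndarray
    domain_labels: np.ndarray
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.class_labels = np.asarray(self.class_labels, dtype=np.int64)
        self.domain_labels = np.asarray(self.domain_labels, dtype=np.int64)
        n = len(self.images)
        if not (len(self.class_labels) == len(self.domain_labels) == n):
            raise ValueError("images, class_labels, domain_labels must have equal length")
        if self.images.ndim != 4:
            raise ValueError("images must be (n, H, W, C)")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return int(self.class_labels.max()) + 1 if len(self) else 0

    def subset(self, idx) -> "LabeledImageSet":
        idx = np.asarray(idx, dtype=np.int64)
        man = self.manifest.iloc[idx].reset_index(drop=True) if len(self.manifest) else self.manifest
        return LabeledImageSet(self.images[idx], self.class_labels[idx],
                               self.domain_labels[idx], man)

    def validate(self) -> None:
        """Check the container invariants; raise on violation."""
        if float(np.abs(self.images).max(initial=0.0)) > 1.0 + 1e-6:
            raise ValueError("pixel values outside [-1, 1]")
        if len(self) and (self.class_labels.min() < 0 or self.domain_labels.min() < 0):
            raise ValueError("negative labels")

    def to_nchw(self) -> np.ndarray:
        return np.ascontiguousarray(self.images.transpose(0, 3, 1, 2))


def _nearest_resize(arr: np.ndarray, size: tuple) -> np.ndarray:
    """Nearest-neighbor resize with floor-index sampling:
    out[i, j] = in[floor(i*h/H), floor(j*w/W)]."""
    h, w = arr.shape[:2]
    rows = np.arange(size[0]) * h // size[0]
    cols = np.arange(size[1]) * w // size[1]
    return arr[rows][:, cols]


def load_dataset(manifest_path, image_size=(32, 32), interp: str = "nearest",
                 n_classes: int | None = None, n_domains: int | None = None) -> LabeledImageSet:
    """Read a PNG + CSV-manifest dataset, resize, and normalize to [-1, 1].

    Grayscale images are replicated to three channels.  A label outside the
    declared range rejects the whole manifest; a missing image file raises
    with the offending path.
    """
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path)
    required = {"path", "class", "domain"}
    if not required.issubset(man.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if n_classes is not None and ((man["class"] < 0) | (man["class"] >= n_classes)).any():
        raise ValueError(f"manifest rejected: class label outside [0, {n_classes})")
    if n_domains is not None and ((man["domain"] < 0) | (man["domain"] >= n_domains)).any():
        raise ValueError(f"manifest rejected: domain label outside [0, {n_domains})")
    if interp not in _INTERP:
        raise ValueError(f"interp must be one of {sorted(_INTERP)}")
    root = manifest_path.parent
    imgs = []
    for p in man["path"]:
        fp = root / p
        if not fp.exists():
            raise FileNotFoundError(f"image referenced by manifest not found: {fp}")
        with Image.open(fp) as im:
            if interp == "nearest":
                arr = np.asarray(im, dtype=np.float32) / 255.0
                arr = _nearest_resize(arr, image_size)
            else:
                im = im.resize(image_size[::-1], _INTERP[interp])
                arr = np.asarray(im, dtype=np.float32) / 255.0
        if arr.ndim == 2:
            arr = np.repeat(arr[:, :, None], 3, axis=2)
        elif arr.shape[2] == 4:
            arr = arr[:, :, :3]
        imgs.append(arr)
    images = normalize(np.stack(imgs))
    return LabeledImageSet(images, man["class"].to_numpy(), man["domain"].to_numpy(), man)


def save_dataset(dataset: LabeledImageSet, out_dir, prefix: str = "img") -> Path:
    """Write PNG images and a ``manifest.csv``; returns the manifest path.

    Pixel values are denormalized and quantized to 8 bits.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(dataset.images):
        arr = np.clip(denormalize(img) * 255.0 + 0.5, 0, 255).astype(np.uint8)
        rel = f"images/{prefix}_{i:06d}.png"
        Image.fromarray(arr).save(out_dir / rel)
        paths.append(rel)
    man = pd.DataFrame({"path": paths, "class": dataset.class_labels,
                        "domain": dataset.domain_labels})
    mp = out_dir / "manifest.csv"
    man.to_csv(mp, index=False)
    return mp


@dataclass
class SplitSpec:
    train: float = 0.80
    val: float = 0.10
    test: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def _largest_remainder(n: int, fracs) -> list[int]:
    raw = [n * f for f in fracs]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder first
    for j in order[:rem]:
        base[j] += 1
    return base


def split_dataset(dataset: LabeledImageSet, spec: SplitSpec | None = None):
    """Stratified train/val/test partition.

    Items are shuffled and allocated within each (class, domain) stratum by
    largest-remainder apportionment, so each split's per-stratum count is
    within one item of proportional.  Deterministic for a fixed seed.
    """
    spec = spec or SplitSpec()
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)
    fracs = (spec.train, spec.val, spec.test)
    buckets: list[list[int]] = [[], [], []]
    keys = dataset.class_labels * (dataset.domain_labels.max() + 1) + dataset.domain_labels
    for key in np.unique(keys):
        idx = np.flatnonzero(keys == key)
        if len(idx) < 3:
            warnings.warn(f"stratum {key} has fewer than 3 items; best-effort assignment")
        idx = rng.permutation(idx)
        counts = _largest_remainder(len(idx), fracs)
        pos = 0
        for b, c in zip(buckets, counts):
            b.extend(idx[pos:pos + c])
            pos += c
    return tuple(dataset.subset(np.sort(b)) for b in buckets)


@dataclass
class BatchPlan:
    batch_size: int = 32
    balance_by_class: bool = False
    even_domain_split: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.even_domain_split and self.batch_size < 2:
            raise ValueError("even_domain_split requires batch_size >= 2")


@dataclass
class MixedBatch:
    """One mixed source/target batch.

    Target class labels are deliberately absent: adaptation is unsupervised
    and the batch stream is the only data interface the trainer sees.
    """

    src_images: np.ndarray
    src_classes: np.ndarray
    src_domains: np.ndarray
    tgt_images: np.ndarray
    tgt_domains: np.ndarray


def _balanced_choice(rng, class_labels: np.ndarray, n: int) -> np.ndarray:
    """Sample n indices with classes balanced up to remainder."""
    classes = np.unique(class_labels)
    counts = _largest_remainder(n, [1.0 / len(classes)] * len(classes))
    order = rng.permutation(len(classes))
    out = []
    for j, c in enumerate(classes[order]):
        pool = np.flatnonzero(class_labels == c)
        k = counts[j]
        if k:
            out.append(rng.choice(pool, size=k, replace=True))
    return rng.permutation(np.concatenate(out))


def iterate_batches(source: LabeledImageSet, target, plan: BatchPlan):
    """Unbounded stream of mixed batches, sampling with replacement.

    ``target`` may be a LabeledImageSet or a plain image array; only its
    images are ever read.  With ``even_domain_split`` each batch holds
    floor(B/2) source and ceil(B/2) target items.
    """
    tgt_images = target.images if hasattr(target, "images") else np.asarray(target)
    tgt_domains = (target.domain_labels if hasattr(target, "domain_labels")
                   else np.full(len(tgt_images), -1))
    if len(source) == 0 or len(tgt_images) == 0:
        raise ValueError("source and target must be nonempty")
    rng = np.random.default_rng(plan.seed)
    n_src = plan.batch_size // 2 if plan.even_domain_split else plan.batch_size
    n_tgt = plan.batch_size - n_src if plan.even_domain_split else plan.batch_size
    while True:
        if plan.balance_by_class:
            si = _balanced_choice(rng, source.class_labels, n_src)
        else:
            si = rng.integers(0, len(source), n_src)
        ti = rng.integers(0, len(tgt_images), n_tgt)
        yield MixedBatch(source.images[si], source.class_labels[si],
                         source.domain_labels[si], tgt_images[ti], tgt_domains[ti])
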