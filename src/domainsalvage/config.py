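"""Run configuration: one serializable object covering data generation,
architectures, training schedules and evaluation, plus named presets.

Presets
-------
``desk``        32x32 digit-like task, 2,000/250/250 images per domain,
                3,000 adaptation iterations, batch 32 — a desk-scale run.
``paper-digit`` the digit-scale protocol (200K iterations, batch 200,
                4 residual blocks, LeNet-style task net).
``paper-cxr``   the radiograph-scale protocol (224x224, 9 residual blocks,
                batch 20, dense-head task net with class-balanced batches
                and affine augmentation).
``micro``       a minutes-scale smoke configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .losses import LossWeights
from .networks import TaskNetSpec
from .synth import DomainStyle, TaskSpec, strong_shift_pair, style_ladder
from .train import AdaptationConfig, ClassifierConfig

__all__ = ["RunConfig", "preset", "PRESETS", "save_config", "load_config"]


@dataclass
class RunConfig:
    task: TaskSpec = field(default_factory=TaskSpec)
    styles: list = field(default_factory=strong_shift_pair)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    adaptation: AdaptationConfig = field(default_factory=AdaptationConfig)
    task_net: TaskNetSpec | None = None          # None: inferred from the task
    source_domain: int = 0
    target_domain: int = 1
    n_boot: int = 1000
    rep_size: int = 1000
    global_fractions: tuple = (1.0,)   # paper-style axis: (0.001, 0.01, 0.1, 1.0)
    split_seed: int = 0
    seed: int = 0
    name: str = "run"


def preset(name: str) -> RunConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name]()


def _desk() -> RunConfig:
    return RunConfig(
        task=TaskSpec(task="digitlike", n_per_domain=2500, image_size=32),
        styles=strong_shift_pair(),
        classifier=ClassifierConfig(lr=1e-3, batch_size=128),
        adaptation=AdaptationConfig(total_iters=3000, batch_size=32,
                                    gen_base=16, n_res=4, disc_base=16),
        name="desk",
    )


def _paper_digit() -> RunConfig:
    return RunConfig(
        task=TaskSpec(task="digitlike", n_per_domain=50000, image_size=32),
        styles=style_ladder(),
        classifier=ClassifierConfig(lr=1e-3, batch_size=128),
        adaptation=AdaptationConfig(total_iters=200_000, batch_size=200,
                                    gen_base=64, n_res=4, disc_base=64),
        name="paper-digit",
    )


def _paper_cxr() -> RunConfig:
    return RunConfig(
        task=TaskSpec(task="opacitylike", n_per_domain=50000, image_size=224),
        styles=style_ladder(),
        classifier=ClassifierConfig(lr=2e-4, batch_size=50, weight_decay=5e-4,
                                    augment=True, balance_by_class=True),
        adaptation=AdaptationConfig(total_iters=200_000, batch_size=20,
                                    gen_base=64, n_res=9, disc_base=64,
                                    balance_by_class=True),
        task_net=TaskNetSpec(backbone="dense_head", n_classes=2, image_size=224),
        name="paper-cxr",
    )


def _micro() -> RunConfig:
    return RunConfig(
        task=TaskSpec(task="digitlike", n_per_domain=400, image_size=32),
        styles=strong_shift_pair(),
        classifier=ClassifierConfig(batch_size=64, max_epochs=15, patience=5),
        adaptation=AdaptationConfig(total_iters=60, batch_size=16,
                                    gen_base=8, n_res=2, disc_base=8),
        n_boot=200, rep_size=250,
        name="micro",
    )


PRESETS = {"desk": _desk, "paper-digit": _paper_digit, "paper-cxr": _paper_cxr,
           "micro": _micro}


# ---------------------------------------------------------------------------
# YAML (de)serialization
# ---------------------------------------------------------------------------

def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, type):
        return obj.__name__
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_config(cfg: RunConfig, path) -> None:
    doc = _plain(cfg)
    doc["task_net"] = _plain(cfg.task_net) if cfg.task_net else None
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


_DTYPES = {"float32": np.float32, "float64": np.float64}


def load_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    styles = [DomainStyle(**{**s, "channel_gain": tuple(s["channel_gain"]),
                             "channel_offset": tuple(s["channel_offset"])})
              for s in doc.pop("styles")]
    ad = doc.pop("adaptation")
    ad["weights"] = LossWeights(**ad["weights"])
    ad["betas"] = tuple(ad["betas"])
    cl = doc.pop("classifier")
    cl["betas"] = tuple(cl["betas"])
    tn = doc.pop("task_net", None)
    if tn:
        tn["hidden"] = tuple(tn["hidden"])
        tn["dtype"] = _DTYPES[tn["dtype"]]
    if "global_fractions" in doc:
        doc["global_fractions"] = tuple(doc["global_fractions"])
    return RunConfig(task=TaskSpec(**doc.pop("task")), styles=styles,
                     classifier=ClassifierConfig(**cl),
                     adaptation=AdaptationConfig(**ad),
                     task_net=TaskNetSpec(**tn) if tn else None, **doc)
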