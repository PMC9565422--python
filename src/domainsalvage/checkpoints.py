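"""Checkpoint container: one ``.npz`` file holding the architecture spec
(as JSON), every parameter/running-statistic array, and optional metadata
such as the training iteration."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .networks import (DiscriminatorSpec, GeneratorSpec, TaskNetSpec,
                       build_discriminator, build_generator, build_task_net)
from .nn import Module

__all__ = ["save_checkpoint", "load_checkpoint"]

_SPECS = {"GeneratorSpec": (GeneratorSpec, build_generator),
          "DiscriminatorSpec": (DiscriminatorSpec, build_discriminator),
          "TaskNetSpec": (TaskNetSpec, build_task_net)}
_DTYPES = {"float32": np.float32, "float64": np.float64}


def save_checkpoint(net: Module, path, meta: dict | None = None) -> None:
    spec = net.spec
    doc = dataclasses.asdict(spec)
    doc["dtype"] = np.dtype(spec.dtype).name
    header = {"spec_type": type(spec).__name__, "spec": doc, "meta": meta or {}}
    state = net.state_dict()
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[Module, dict]:
    """Rebuild the network from a checkpoint; returns (net, meta)."""
    with np.load(Path(path), allow_pickle=False) as z:
        header = json.loads(bytes(z["__header__"]))
        state = {k: z[k] for k in z.files if k != "__header__"}
    doc = header["spec"]
    doc["dtype"] = _DTYPES[doc["dtype"]]
    for key in ("hidden",):
        if key in doc and isinstance(doc[key], list):
            doc[key] = tuple(doc[key])
    cls, builder = _SPECS[header["spec_type"]]
    net = builder(cls(**doc))
    net.load_state_dict(state)
    net.eval()
    return net, header["meta"]
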