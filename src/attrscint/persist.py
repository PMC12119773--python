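"""Save/load trained models (numpy weight archives + JSON metadata)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._nn import make_small_cnn, make_small_segnet
from .classification import ClsModel, ClsTrainConfig, TaskSpec
from .segmentation import SegModel, SegTrainConfig


def _state_of(model):
    return model.best_state if model.best_state is not None else model.net.get_state()


def save_model(path, model) -> None:
    path = Path(path)
    state = _state_of(model)
    arrays = {f"param_{i}": a for i, a in enumerate(state)}
    if isinstance(model, SegModel):
        meta = {"kind": "seg", "structure": model.structure,
                "cfg": dataclasses.asdict(model.cfg)}
    elif isinstance(model, ClsModel):
        meta = {"kind": "cls", "provenance": list(model.provenance),
                "task": {"name": model.task.name,
                         "positive_grades": sorted(model.task.positive_grades)},
                "cfg": dataclasses.asdict(model.cfg)}
    else:
        raise TypeError(f"cannot save {type(model).__name__}")
    np.savez(path, **arrays)
    Path(str(path) + ".json").write_text(json.dumps(meta, default=str))


def load_model(path):
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
        state = [z[f"param_{i}"] for i in range(len(z.files))]
    rng = np.random.default_rng(0)
    if meta["kind"] == "seg":
        cfg_d = meta["cfg"]
        cfg_d["patch_hw"] = tuple(cfg_d["patch_hw"]) if cfg_d["patch_hw"] else None
        cfg = SegTrainConfig(**cfg_d)
        net = make_small_segnet(rng)
        model = SegModel(net=net, structure=meta["structure"], cfg=cfg)
    else:
        cfg_d = meta["cfg"]
        cfg_d["input_hw"] = tuple(cfg_d["input_hw"])
        cfg = ClsTrainConfig(**cfg_d)
        task = TaskSpec(meta["task"]["name"],
                        frozenset(meta["task"]["positive_grades"]))
        net = make_small_cnn(rng)
        model = ClsModel(net=net, task=task, cfg=cfg,
                         provenance=tuple(meta["provenance"]))
    model.net.set_state(state)
    model.best_state = state
    return model
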