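"""Checkpoints: trainable parameters + model geometry, nothing else.

The frozen encoder is reconstructed from its builder arguments and seed, so
a checkpoint stores only what training changed (adapter + head arrays) plus
the configuration needed to rebuild the model.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Union

import numpy as np

from .adapters import AdapterStackConfig
from .training import SegmentationModel, TrainConfig, TrainedModel
from .encoder import build_surrogate_encoder

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(trained: TrainedModel, path: Union[str, Path]) -> None:
    model = trained.model
    enc = model.encoder
    meta = {
        "encoder": {
            "name": "surrogate",
            "stage_dims": list(enc.stage_dims),
            "stage_depths": list(enc.stage_depths),
            "patch_stride": enc.patch_stride,
            "seed": enc.seed,
        },
        "adapter": {
            "stage_dims": list(model.adapter_config.stage_dims),
            "stage_depths": list(model.adapter_config.stage_depths),
            "reduction": model.adapter_config.reduction,
            "fft_cutoff_fraction": model.adapter_config.fft_cutoff_fraction,
            "clamp_bottleneck": model.adapter_config.clamp_bottleneck,
        },
        "head_channels": model.head_channels,
        "model_seed": model.seed,
        "train_config": asdict(trained.config),
        "loss_history": trained.loss_history,
    }
    arrays = {}
    for t in model.trainable_parameters():
        if t.name is None:
            raise ValueError("trainable parameter without a name cannot be saved")
        arrays[t.name] = t.data
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: Union[str, Path]) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    enc_meta = meta["encoder"]
    if enc_meta["name"] != "surrogate":
        raise ValueError(
            f"checkpoint encoder {enc_meta['name']!r} requires an external plugin"
        )
    encoder = build_surrogate_encoder(
        enc_meta["stage_dims"], enc_meta["stage_depths"],
        enc_meta["patch_stride"], seed=enc_meta["seed"],
    )
    adapter_config = AdapterStackConfig(
        stage_dims=tuple(meta["adapter"]["stage_dims"]),
        stage_depths=tuple(meta["adapter"]["stage_depths"]),
        reduction=meta["adapter"]["reduction"],
        fft_cutoff_fraction=meta["adapter"]["fft_cutoff_fraction"],
        clamp_bottleneck=meta["adapter"]["clamp_bottleneck"],
    )
    model = SegmentationModel(encoder, adapter_config,
                              head_channels=meta["head_channels"],
                              seed=meta["model_seed"])
    by_name = {t.name: t for t in model.trainable_parameters()}
    for name, arr in arrays.items():
        if name not in by_name:
            raise ValueError(f"checkpoint parameter {name!r} has no slot in the model")
        if by_name[name].data.shape != arr.shape:
            raise ValueError(f"checkpoint parameter {name!r} has shape {arr.shape}, "
                             f"model expects {by_name[name].data.shape}")
        by_name[name].data = arr.astype(np.float64)
    config = TrainConfig(**meta["train_config"])
    return TrainedModel(model=model, config=config,
                        loss_history=list(meta["loss_history"]))
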