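"""Run configuration: nested defaults, YAML loading, per-stage seed fan-out."""

from __future__ import annotations

import copy
import dataclasses
import zlib
from pathlib import Path
from typing import Any

import yaml

from .binarize_fuse import MIN_COMPONENT, ThresholdConfig
from .enhancement import CHANNEL2_DEFAULTS, CHANNEL3_DEFAULTS, ChannelSpec
from .preprocess import PreprocessConfig
from .training import DEFAULT_LR_STAGES, TrainConfig
from .unet import UNetSpec

__all__ = ["RunConfig", "default_config_dict", "load_config", "stage_seed"]


def default_config_dict() -> dict[str, Any]:
    """The fully-resolved default configuration as a plain dict."""
    return {
        "seed": 0,
        "preprocess": {"clahe_clip_limit": 2.0, "clahe_tile_grid": [8, 8], "gamma": 1.2},
        "channels": {
            1: {"channel": 1, "closing_radius": 11},
            2: {"channel": 2, "l": 10.8, "s": 1.9, "n_dirs": 8, "blackhat_radius": 11},
            3: {"channel": 3, "l": 5.0, "s": 0.1, "n_dirs": 18, "blackhat_radius": 11},
        },
        "unet": {"input_side": 576, "base": 64, "negative_slope": 0.01},
        "train": {
            "epochs": 30,
            "batch_size": 2,
            "momentum": 0.9,
            "weight_decay": 0.0,
            "lam": 0.5,
            "lr_stages": [list(s) for s in DEFAULT_LR_STAGES],
            "augment": True,
            "val_fraction": 0.1,
        },
        "threshold": {"b": -15.0, "w_m": 15, "w_n": 15},
        "postprocess": {"min_component": MIN_COMPONENT},
    }


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in out:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _merge(out[key], val, here)
        else:
            out[key] = val
    return out


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Resolved configuration objects for every pipeline stage."""

    raw: dict[str, Any]
    seed: int
    preprocess: PreprocessConfig
    channels: dict[int, ChannelSpec]
    unet: UNetSpec
    train: TrainConfig
    threshold: ThresholdConfig
    min_component: int

    @classmethod
    def from_dict(cls, doc: dict[str, Any] | None = None) -> "RunConfig":
        merged = _merge(default_config_dict(), doc or {})
        seed = int(merged["seed"])
        pre = merged["preprocess"]
        channels = {}
        for ch, block in merged["channels"].items():
            ch = int(ch)
            channels[ch] = ChannelSpec(**{**block, "channel": ch})
        un = merged["unet"]
        tr = merged["train"]
        return cls(
            raw=merged,
            seed=seed,
            preprocess=PreprocessConfig(
                clahe_clip_limit=pre["clahe_clip_limit"],
                clahe_tile_grid=tuple(pre["clahe_tile_grid"]),
                gamma=pre["gamma"],
            ),
            channels=channels,
            unet=UNetSpec(input_side=un["input_side"], base=un["base"],
                          negative_slope=un["negative_slope"],
                          seed=stage_seed("unet-init", seed)),
            train=TrainConfig(
                epochs=tr["epochs"], batch_size=tr["batch_size"],
                momentum=tr["momentum"], weight_decay=tr["weight_decay"],
                lam=tr["lam"],
                lr_stages=tuple((int(e), float(lr)) for e, lr in tr["lr_stages"]),
                augment=tr["augment"], val_fraction=tr["val_fraction"],
                seed=stage_seed("train", seed),
            ),
            threshold=ThresholdConfig(b=merged["threshold"]["b"],
                                      w_m=merged["threshold"]["w_m"],
                                      w_n=merged["threshold"]["w_n"]),
            min_component=int(merged["postprocess"]["min_component"]),
        )

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.raw, sort_keys=True))


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) if path else {}
    if doc is None:
        doc = {}
    if seed is not None:
        doc["seed"] = seed
    return RunConfig.from_dict(doc)


def stage_seed(stage: str, seed: int) -> int:
    """Deterministic per-stage seed derived from one master seed."""
    return zlib.crc32(f"{stage}:{seed}".encode()) & 0x7FFFFFFF
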