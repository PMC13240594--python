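"""Run configuration: defaults < config file (YAML/TOML) < CLI overrides.

Every default equals the corresponding module-level default; unknown keys
and type mismatches are rejected with errors naming the offending key.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Tuple, Union

import yaml

logger = logging.getLogger("cryofsl")

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class EncoderSection:
    name: str = "surrogate"
    patch_stride: int = 4
    checkpoint: Optional[str] = None


@dataclass
class AdapterSection:
    stage_dims: Tuple[int, ...] = (144, 288, 576, 1152)
    stage_depths: Tuple[int, ...] = (2, 6, 36, 4)
    reduction: int = 32
    fft_cutoff_fraction: float = 0.25
    clamp_bottleneck: bool = False
    seed: Optional[int] = None  # falls back to the global seed


@dataclass
class SynthSection:
    image_shape: Tuple[int, int] = (512, 512)
    n_particles: int = 50
    diameter_px: float = 16.0
    diameter_jitter: float = 0.0
    snr: float = 4.0
    min_separation: float = 24.0
    allow_overlap: bool = False
    n_items: int = 5


@dataclass
class TrainSection:
    input_size: int = 1024
    batch_size: int = 2
    learning_rate: float = 1e-4
    max_epochs: int = 4000
    pos_weight_mode: str = "auto"
    pos_weight: float = 1.0
    threshold: float = 0.5
    head_channels: int = 32


@dataclass
class PostprocessSection:
    expected_diameter_px: float = 16.0
    threshold: float = 0.5
    area_range: Tuple[float, float] = (0.3, 3.0)
    min_circularity: float = 0.6
    peak_scales: Tuple[float, ...] = (1.0, 2.0, 4.0)
    min_peak_distance_frac: float = 0.25
    min_separation_frac: float = 0.6
    dual_pass: bool = True
    drop_border: bool = False


@dataclass
class EvaluateSection:
    match_radius_frac: float = 0.5  # fraction of expected diameter


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "runs"
    encoder: EncoderSection = field(default_factory=EncoderSection)
    adapter: AdapterSection = field(default_factory=AdapterSection)
    synth: SynthSection = field(default_factory=SynthSection)
    train: TrainSection = field(default_factory=TrainSection)
    postprocess: PostprocessSection = field(default_factory=PostprocessSection)
    evaluate: EvaluateSection = field(default_factory=EvaluateSection)


_TUPLE_FIELDS = {"stage_dims", "stage_depths", "image_shape", "area_range",
                 "peak_scales"}


def _assign(obj: Any, key: str, value: Any, path: str) -> None:
    if not hasattr(obj, key) or key.startswith("_"):
        raise ConfigError(f"unknown config key: {path}")
    current = getattr(obj, key)
    if dataclasses.is_dataclass(current):
        if not isinstance(value, dict):
            raise ConfigError(f"{path}: expected a mapping for this section")
        for sub_key, sub_val in value.items():
            _assign(current, sub_key, sub_val, f"{path}.{sub_key}")
        return
    if key in _TUPLE_FIELDS:
        if not isinstance(value, (list, tuple)):
            raise ConfigError(f"{path}: expected a list, got {type(value).__name__}")
        value = tuple(value)
    elif isinstance(current, bool):
        if not isinstance(value, bool):
            raise ConfigError(f"{path}: expected a boolean, got {value!r}")
    elif isinstance(current, int) and not isinstance(current, bool):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{path}: expected an integer, got {value!r}")
        if isinstance(value, float) and not value.is_integer():
            raise ConfigError(f"{path}: expected an integer, got {value!r}")
        value = int(value)
    elif isinstance(current, float):
        if isinstance(value, str):
            # YAML leaves bare exponents like "2e-4" as strings
            try:
                value = float(value)
            except ValueError:
                raise ConfigError(f"{path}: expected a number, got {value!r}") from None
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{path}: expected a number, got {value!r}")
        value = float(value)
    elif isinstance(current, str):
        if not isinstance(value, str):
            raise ConfigError(f"{path}: expected a string, got {value!r}")
    setattr(obj, key, value)


def _read_file(path: Union[str, Path]) -> Dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".toml":
        import tomllib

        data = tomllib.loads(text)
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return data


def load_config(path: Optional[Union[str, Path]] = None,
                overrides: Sequence[str] = ()) -> RunConfig:
    """Resolve a RunConfig from defaults, an optional file and key=value
    overrides in dotted form (e.g. ``train.learning_rate=2e-4``)."""
    cfg = RunConfig()
    if path is not None:
        for key, value in _read_file(path).items():
            _assign(cfg, key, value, key)
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not of the form key=value")
        dotted, raw = item.split("=", 1)
        value = yaml.safe_load(raw)
        parts = dotted.strip().split(".")
        obj, walked = cfg, []
        for part in parts[:-1]:
            walked.append(part)
            if not hasattr(obj, part):
                raise ConfigError(f"unknown config key: {'.'.join(walked)}")
            obj = getattr(obj, part)
            if not dataclasses.is_dataclass(obj):
                raise ConfigError(f"{'.'.join(walked)} is not a config section")
        _assign(obj, parts[-1], value, dotted.strip())
    logger.info("resolved config: %s", dataclasses.asdict(cfg))
    return cfg
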