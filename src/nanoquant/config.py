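"""Pipeline configuration: one YAML file, sections per stage.

``validate_config`` loads a YAML file (or a plain dict), fills defaults,
normalizes axis conventions and reports *all* problems at once rather than
failing on the first.  Two presets are shipped: ``full`` carries the
full-scale defaults (500^3 inference tiles, 128^3 training crops, batch 2,
lr 1e-4, 5 folds, 1000 epochs, 16x16 lateral x 4 axial density window) for
real whole-body scans, and ``desk`` overrides the compute-heavy ones so a
complete run finishes in minutes on one CPU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .density import DensityConfig
from .evaluation import MatchConfig
from .phantom import PhantomConfig
from .segmentation import TrainConfig, UNetConfig

__all__ = ["PipelineConfig", "ConfigError", "validate_config"]


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass
class TilingConfig:
    max_patch_shape: tuple[int, int, int] = (500, 500, 500)
    halo: tuple[int, int, int] = (32, 32, 32)


@dataclass
class QuantifyConfig:
    connectivity: int = 26
    contrast_mode: str = "relative"
    min_voxels: int = 0
    allow_background_fallback: bool = False


@dataclass
class PipelineConfig:
    out_dir: Path = Path("nanoquant_run")
    volume: Path | None = None  # pre-existing inputs override the phantom stage
    organs: Path | None = None
    seed: int = 0
    preset: str = "full"
    volume_format: str = "tiff_stack"
    threshold_stub: float | None = None  # use the stub model instead of training
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    unet: UNetConfig = field(default_factory=UNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_training_patches: int = 30
    training_patch_shape: tuple[int, int, int] = (64, 64, 64)
    tiling: TilingConfig = field(default_factory=TilingConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    density: DensityConfig = field(default_factory=DensityConfig)
    evaluation: MatchConfig = field(default_factory=MatchConfig)


_DESK_UNET = dict(encoder_levels=3, base_channels=8, patch_shape=(32, 32, 32))
_DESK_TRAIN = dict(folds=2, epochs=20, learning_rate=0.01, momentum=0.9,
                   crop_shape=(32, 32, 32))
_DESK_TILING = dict(max_patch_shape=(64, 64, 64), halo=(8, 8, 8))


def _as_shape(value, key, errors, n=3):
    try:
        t = tuple(int(v) for v in value)
        if len(t) != n:
            raise ValueError
        return t
    except (TypeError, ValueError):
        errors.append(f"{key}: expected {n} integers, got {value!r}")
        return None


def validate_config(source) -> PipelineConfig:
    """Load + validate a pipeline config from a YAML path or a dict.

    Unknown keys produce warnings; type and constraint violations are
    collected and raised together as :class:`ConfigError`.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        raise TypeError(f"config source must be a path or dict, got {type(source)}")

    errors: list[str] = []
    known = {
        "out_dir", "volume", "organs", "seed", "preset", "volume_format",
        "threshold_stub", "phantom", "model", "tiling", "quantify",
        "density", "evaluation", "n_training_patches", "training_patch_shape",
    }
    for key in raw:
        if key not in known:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)

    preset = raw.get("preset", "full")
    if preset not in ("full", "desk"):
        errors.append(f"preset: must be 'full' or 'desk', got {preset!r}")
        preset = "full"

    cfg = PipelineConfig(preset=preset)
    if preset == "desk":
        cfg.unet = UNetConfig(**_DESK_UNET)
        cfg.train = TrainConfig(**_DESK_TRAIN)
        cfg.tiling = TilingConfig(**_DESK_TILING)

    if "out_dir" in raw:
        cfg.out_dir = Path(raw["out_dir"])
    if raw.get("volume"):
        cfg.volume = Path(raw["volume"])
    if raw.get("organs"):
        cfg.organs = Path(raw["organs"])
    if "seed" in raw:
        try:
            cfg.seed = int(raw["seed"])
        except (TypeError, ValueError):
            errors.append(f"seed: expected an integer, got {raw['seed']!r}")
    if "volume_format" in raw:
        if raw["volume_format"] not in ("tiff_stack", "nifti"):
            errors.append(f"volume_format: unknown format {raw['volume_format']!r}")
        else:
            cfg.volume_format = raw["volume_format"]
    if "threshold_stub" in raw and raw["threshold_stub"] is not None:
        try:
            cfg.threshold_stub = float(raw["threshold_stub"])
        except (TypeError, ValueError):
            errors.append(f"threshold_stub: expected a number, got {raw['threshold_stub']!r}")
    if "n_training_patches" in raw:
        n = raw["n_training_patches"]
        if not isinstance(n, int) or n < 1:
            errors.append(f"n_training_patches: expected a positive integer, got {n!r}")
        else:
            cfg.n_training_patches = n
    if "training_patch_shape" in raw:
        s = _as_shape(raw["training_patch_shape"], "training_patch_shape", errors)
        if s:
            cfg.training_patch_shape = s

    # -- phantom section ----------------------------------------------------
    ph = raw.get("phantom", {}) or {}
    ph_kwargs = {}
    if "shape" in ph:
        s = _as_shape(ph["shape"], "phantom.shape", errors)
        if s:
            ph_kwargs["shape"] = s
    for key in ("outside_background", "noise_sigma", "poisson_scale", "footprint_threshold"):
        if key in ph:
            try:
                ph_kwargs[key] = float(ph[key])
            except (TypeError, ValueError):
                errors.append(f"phantom.{key}: expected a number, got {ph[key]!r}")
    if "particles_per_organ" in ph:
        v = ph["particles_per_organ"]
        if isinstance(v, dict):
            ph_kwargs["particles_per_organ"] = {int(k): int(n) for k, n in v.items()}
        elif isinstance(v, int) and v >= 0:
            ph_kwargs["particles_per_organ"] = v
        else:
            errors.append(f"phantom.particles_per_organ: expected int or mapping, got {v!r}")
    for key in ("amplitude_range", "sigma_lateral_range", "sigma_axial_range"):
        if key in ph:
            s = _as_pair(ph[key], f"phantom.{key}", errors)
            if s:
                ph_kwargs[key] = s
    if "background" in ph:
        try:
            ph_kwargs["background"] = {int(k): float(v) for k, v in ph["background"].items()}
        except (TypeError, ValueError, AttributeError):
            errors.append(f"phantom.background: expected mapping label -> level")
    try:
        cfg.phantom = PhantomConfig(**ph_kwargs)
        cfg.phantom.validate()
    except ValueError as exc:
        errors.append(f"phantom: {exc}")

    # -- model section ------------------------------------------------------
    model = raw.get("model", {}) or {}
    unet_raw = dict(model.get("unet", {}) or {})
    train_raw = dict(model.get("train", {}) or {})
    if unet_raw:
        if "patch_shape" in unet_raw:
            s = _as_shape(unet_raw["patch_shape"], "model.unet.patch_shape", errors)
            unet_raw["patch_shape"] = s if s else (128, 128, 128)
        base = _DESK_UNET if preset == "desk" else {}
        try:
            cfg.unet = UNetConfig(**{**base, **unet_raw})
        except (TypeError, ValueError) as exc:
            errors.append(f"model.unet: {exc}")
    if train_raw:
        if "crop_shape" in train_raw:
            s = _as_shape(train_raw["crop_shape"], "model.train.crop_shape", errors)
            train_raw["crop_shape"] = s if s else (128, 128, 128)
        base = _DESK_TRAIN if preset == "desk" else {}
        try:
            cfg.train = TrainConfig(**{**base, **train_raw})
        except (TypeError, ValueError) as exc:
            errors.append(f"model.train: {exc}")

    # -- tiling / quantify / density / evaluation ---------------------------
    til = raw.get("tiling", {}) or {}
    til_kwargs = {}
    for key in ("max_patch_shape", "halo"):
        if key in til:
            s = _as_shape(til[key], f"tiling.{key}", errors)
            if s:
                til_kwargs[key] = s
    if til_kwargs:
        base = _DESK_TILING if preset == "desk" else {}
        cfg.tiling = TilingConfig(**{**base, **til_kwargs})
        if any(m < 1 for m in cfg.tiling.max_patch_shape):
            errors.append("tiling.max_patch_shape: entries must be >= 1")
        if any(h < 0 for h in cfg.tiling.halo):
            errors.append("tiling.halo: entries must be >= 0")

    q = raw.get("quantify", {}) or {}
    qc = QuantifyConfig()
    if "connectivity" in q:
        if q["connectivity"] not in (6, 18, 26):
            errors.append(f"quantify.connectivity: must be 6, 18 or 26, got {q['connectivity']!r}")
        else:
            qc.connectivity = q["connectivity"]
    if "contrast_mode" in q:
        if q["contrast_mode"] not in ("relative", "absolute"):
            errors.append(f"quantify.contrast_mode: unknown mode {q['contrast_mode']!r}")
        else:
            qc.contrast_mode = q["contrast_mode"]
    if "min_voxels" in q:
        if not isinstance(q["min_voxels"], int) or q["min_voxels"] < 0:
            errors.append(f"quantify.min_voxels: expected int >= 0, got {q['min_voxels']!r}")
        else:
            qc.min_voxels = q["min_voxels"]
    if "allow_background_fallback" in q:
        qc.allow_background_fallback = bool(q["allow_background_fallback"])
    cfg.quantify = qc

    d = raw.get("density", {}) or {}
    d_kwargs = {}
    if "window" in d:
        s = _as_shape(d["window"], "density.window", errors)
        if s:
            d_kwargs["window"] = s
    if "stride" in d and d["stride"] is not None:
        s = _as_shape(d["stride"], "density.stride", errors)
        if s:
            d_kwargs["stride"] = s
    if "gaussian_sigma" in d and d["gaussian_sigma"] is not None:
        try:
            d_kwargs["gaussian_sigma"] = tuple(float(v) for v in d["gaussian_sigma"])
        except (TypeError, ValueError):
            errors.append(f"density.gaussian_sigma: expected 3 numbers")
    if "boundary" in d:
        d_kwargs["boundary"] = d["boundary"]
    try:
        cfg.density = DensityConfig(**d_kwargs)
    except ValueError as exc:
        errors.append(f"density: {exc}")

    e = raw.get("evaluation", {}) or {}
    e_kwargs = {}
    if "criterion" in e:
        e_kwargs["criterion"] = e["criterion"]
    if "iou_threshold" in e:
        try:
            e_kwargs["iou_threshold"] = float(e["iou_threshold"])
        except (TypeError, ValueError):
            errors.append(f"evaluation.iou_threshold: expected a number")
    try:
        cfg.evaluation = MatchConfig(**e_kwargs)
    except ValueError as exc:
        errors.append(f"evaluation: {exc}")

    if errors:
        raise ConfigError(errors)
    return cfg


def _as_pair(value, key, errors):
    try:
        t = tuple(float(v) for v in value)
        if len(t) != 2:
            raise ValueError
        return t
    except (TypeError, ValueError):
        errors.append(f"{key}: expected 2 numbers, got {value!r}")
        return None
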