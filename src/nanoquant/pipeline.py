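"""End-to-end workflow: simulate -> train -> predict -> quantify -> density -> evaluate.

Every stage reads its declared inputs from the run directory and writes its
artifacts back there, so any stage can be re-run in isolation and a
complete rerun with the same configuration and seed reproduces the tables
and summaries byte-for-byte.  A manifest records the resolved
configuration, seeds and a checksum for every artifact produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import PipelineConfig
from .density import contrast_volume, block_density, smooth_density
from .evaluation import evaluate_dataset, match_instances
from .phantom import generate_phantom, make_training_set
from .quantify import (
    INSTANCE_COLUMNS,
    estimate_background,
    label_instances,
    measure_instances,
    summarize_organs,
)
from .segmentation import ModelEnsemble, ThresholdModel, predict_volume, train
from .volume_io import (
    LabelVolume,
    VoxelGrid,
    plan_tiles,
    read_organ_names,
    read_volume,
    write_organ_names,
    write_volume,
)

__all__ = ["run_all", "STAGES", "RunManifest"]

log = logging.getLogger("nanoquant")

STAGES = ("simulate", "train", "predict", "quantify", "density", "evaluate")

_EXT = {"tiff_stack": ".tif", "nifti": ".nii"}


@dataclasses.dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages_run: list[str]
    artifacts: dict[str, str]  # relative path -> sha256
    timestamps: dict[str, float]
    complete: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_snapshot(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, str, int, float, bool)) or obj is None:
            return obj
        return str(obj)

    return {f.name: enc(getattr(config, f.name)) for f in dataclasses.fields(config)}


def run_all(config: PipelineConfig, stages: list[str] | None = None) -> RunManifest:
    """Execute the requested stages in pipeline order.

    ``stages`` defaults to all six.  A stage failure aborts the run with
    the failing stage named; artifacts written so far are kept and the
    manifest marks the run incomplete.
    """
    if stages is None:
        stages = list(STAGES)
    else:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        stages = [s for s in STAGES if s in set(stages)]

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = _EXT[config.volume_format]
    manifest = RunManifest(
        config=_config_snapshot(config),
        version=__version__,
        seed=config.seed,
        stages_run=[],
        artifacts={},
        timestamps={},
        complete=False,
    )

    def record(path: Path) -> None:
        manifest.artifacts[str(path.relative_to(out))] = _sha256(path)

    def finish(stage: str) -> None:
        manifest.stages_run.append(stage)
        manifest.timestamps[stage] = time.time()

    try:
        for stage in stages:
            log.info("stage %s starting", stage)
            if stage == "simulate":
                _stage_simulate(config, out, ext, record)
            elif stage == "train":
                _stage_train(config, out, record)
            elif stage == "predict":
                _stage_predict(config, out, ext, record)
            elif stage == "quantify":
                _stage_quantify(config, out, ext, record)
            elif stage == "density":
                _stage_density(config, out, ext, record)
            elif stage == "evaluate":
                _stage_evaluate(config, out, ext, record)
            finish(stage)
        manifest.complete = True
    except Exception as exc:
        _write_manifest(manifest, out)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: RunManifest, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, out: Path, ext: str, record) -> None:
    sample = generate_phantom(config.phantom, config.seed)
    write_volume(sample.volume, out / f"volume{ext}", config.volume_format)
    write_volume(sample.organs, out / f"organs{ext}", config.volume_format)
    write_volume(sample.gt_instances, out / f"gt_instances{ext}", config.volume_format)
    write_organ_names(sample.organs.names, out / "organ_names.json")
    sample.truth.to_csv(out / "truth.csv", index=False)
    with open(out / "phantom_config.yaml", "w") as fh:
        yaml.safe_dump(_config_snapshot(config)["phantom"], fh, sort_keys=True)
    for name in (f"volume{ext}", f"organs{ext}", f"gt_instances{ext}",
                 "organ_names.json", "truth.csv", "phantom_config.yaml"):
        record(out / name)
    log.info("simulate: %d planted particles, %d gt instances",
             len(sample.truth), int(sample.gt_instances.max()))


def _stage_train(config: PipelineConfig, out: Path, record) -> None:
    if config.threshold_stub is not None:
        log.info("train: threshold stub configured, skipping network training")
        return
    pairs = make_training_set(
        config.phantom, config.n_training_patches,
        config.training_patch_shape, config.seed + 1,
    )
    ensemble, logs = train(pairs, config.unet, dataclasses.replace(config.train, seed=config.seed + 2))
    ckpt_dir = out / "checkpoints"
    ckpt_dir.mkdir(exist_ok=True)
    manifest = {"n_folds": len(ensemble.members), "seed": config.seed + 2,
                "config": _config_snapshot(config)["unet"], "folds": []}
    for fold, (member, fold_log) in enumerate(zip(ensemble.members, logs)):
        path = ckpt_dir / f"fold{fold}.npz"
        np.savez(path, *member.get_state())
        best = min(fold_log, key=lambda e: e["val_loss"])
        manifest["folds"].append(
            {"file": path.name, "best_epoch": best["epoch"], "val_loss": best["val_loss"]}
        )
        record(path)
    with open(ckpt_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    record(ckpt_dir / "manifest.json")
    log.info("train: %d folds, best val losses %s", len(logs),
             [round(f["val_loss"], 4) for f in manifest["folds"]])


def _load_model(config: PipelineConfig, out: Path):
    from .segmentation import build_model

    if config.threshold_stub is not None:
        return ThresholdModel(config.threshold_stub)
    ckpt_dir = out / "checkpoints"
    with open(ckpt_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    members = []
    for fold in manifest["folds"]:
        model = build_model(config.unet, 0)
        with np.load(ckpt_dir / fold["file"]) as npz:
            model.set_state([npz[k] for k in npz.files])
        members.append(model)
    return ModelEnsemble(members=members, config=config.unet)


def _read_inputs(config: PipelineConfig, out: Path, ext: str):
    vol_path = config.volume or out / f"volume{ext}"
    org_path = config.organs or out / f"organs{ext}"
    volume = read_volume(vol_path, config.volume_format)
    organs_grid = read_volume(org_path, config.volume_format)
    names_path = out / "organ_names.json"
    names = read_organ_names(names_path) if names_path.exists() else {}
    labels = organs_grid.data.astype(np.int32)
    if not names:
        names = {int(l): f"organ_{int(l)}" for l in np.unique(labels) if l != 0}
    organs = LabelVolume(labels, names)
    return volume, organs


def _stage_predict(config: PipelineConfig, out: Path, ext: str, record) -> None:
    volume, _ = _read_inputs(config, out, ext)
    model = _load_model(config, out)
    grid = plan_tiles(volume.shape, config.tiling.max_patch_shape, config.tiling.halo)
    mask = predict_volume(model, volume, grid)
    write_volume(mask.astype(np.uint8), out / f"mask{ext}", config.volume_format)
    record(out / f"mask{ext}")
    log.info("predict: %d tiles, foreground fraction %.5f", len(grid), mask.mean())


def _stage_quantify(config: PipelineConfig, out: Path, ext: str, record) -> None:
    volume, organs = _read_inputs(config, out, ext)
    mask = read_volume(out / f"mask{ext}", config.volume_format).data.astype(bool)
    inst = label_instances(mask.astype(np.uint8), config.quantify.connectivity)
    backgrounds = estimate_background(
        volume, organs, mask, allow_fallback=config.quantify.allow_background_fallback
    )
    instances = measure_instances(
        volume, organs, inst, backgrounds,
        contrast_mode=config.quantify.contrast_mode,
        min_voxels=config.quantify.min_voxels,
    )
    summaries = summarize_organs(instances, organs, backgrounds)
    write_volume(inst, out / f"instances{ext}", config.volume_format)
    instances.to_csv(out / "instances.csv", index=False, columns=INSTANCE_COLUMNS)
    backgrounds.to_frame().to_csv(out / "backgrounds.csv", index=False)
    with open(out / "organ_summary.json", "w") as fh:
        json.dump([s.to_dict() for s in summaries], fh, indent=2, sort_keys=True)
        fh.write("\n")
    for name in (f"instances{ext}", "instances.csv", "backgrounds.csv", "organ_summary.json"):
        record(out / name)
    log.info("quantify: %d instances across %d organs", len(instances), len(summaries))


def _stage_density(config: PipelineConfig, out: Path, ext: str, record) -> None:
    volume, organs = _read_inputs(config, out, ext)
    mask = read_volume(out / f"mask{ext}", config.volume_format).data.astype(bool)
    backgrounds = estimate_background(
        volume, organs, mask, allow_fallback=config.quantify.allow_background_fallback
    )
    c = contrast_volume(volume, organs, mask, backgrounds)
    raw = block_density(c, config.density)
    smooth = smooth_density(raw, config.density)
    write_volume(smooth.astype(np.float32), out / f"density{ext}", config.volume_format)
    record(out / f"density{ext}")
    log.info("density: total %.3f", float(smooth.sum()))


def _stage_evaluate(config: PipelineConfig, out: Path, ext: str, record) -> None:
    gt_path = out / f"gt_instances{ext}"
    if not gt_path.exists():
        raise FileNotFoundError(
            f"no ground-truth instance volume at {gt_path}; evaluation needs a phantom run"
        )
    gt = read_volume(gt_path, config.volume_format).data.astype(np.int32)
    mask = read_volume(out / f"mask{ext}", config.volume_format).data.astype(bool)
    pred = label_instances(mask.astype(np.uint8), config.quantify.connectivity)
    result = match_instances(pred, gt, config.evaluation)
    report = {"whole_volume": result.to_dict()}
    with open(out / "evaluation.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    record(out / "evaluation.json")
    log.info("evaluate: f1 %.4f (tp %d fp %d fn %d)",
             result.f1, result.tp, result.fp, result.fn)
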