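"""Segmentation stage: normalization, 3D U-Net training and tiled inference.

The protocol mirrors how dot-segmentation networks for whole-body
light-sheet data are trained in practice:

* every patch is min-max normalized to [0, 1] before entering the network;
* training runs k-fold cross-validation over whole annotated patches,
  subsampling random crops (default 128^3 at full scale) at train time,
  batch size 2, loss = (soft-Dice loss + cross-entropy) / 2, SGD;
* per fold the checkpoint with the lowest validation loss is kept, and the
  fold models are ensembled by averaging foreground probabilities;
* whole volumes are processed tile by tile (default cap 500^3 voxels, with
  an optional halo of context) and the per-tile masks stitched together.

Two presets are provided: ``full`` carries the full-scale hyperparameters
(6 levels, 128^3 crops, lr 1e-4, 1000 epochs, 5 folds) and ``desk`` is a
small configuration that trains in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .unet import SGD, UNet3D, dice_ce_loss_and_grad, softmax_fg
from .volume_io import PatchGrid, VoxelGrid, stitch

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "ModelEnsemble",
    "ThresholdModel",
    "normalize_patch",
    "build_model",
    "train",
    "predict_patch",
    "predict_volume",
]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture of the segmentation network.

    ``encoder_levels`` counts resolution levels in the encoder; the decoder
    always has one fewer, so the full-scale network has 6 encoding and 5
    decoding levels.  Input patches must be divisible by
    ``2**(encoder_levels-1)`` per axis.
    """

    encoder_levels: int = 6
    base_channels: int = 32
    max_channels: int = 320
    negative_slope: float = 0.01
    patch_shape: tuple[int, int, int] = (128, 128, 128)

    @property
    def decoder_levels(self) -> int:
        return self.encoder_levels - 1

    def __post_init__(self) -> None:
        if self.encoder_levels < 2:
            raise ValueError("encoder_levels must be >= 2")
        div = 2 ** (self.encoder_levels - 1)
        if any(p % div for p in self.patch_shape):
            raise ValueError(
                f"patch_shape {self.patch_shape} must be divisible by {div} per axis"
            )

    @classmethod
    def tiny(cls, patch_shape: tuple[int, int, int] = (32, 32, 32)) -> "UNetConfig":
        """Desk-scale preset: 3 levels, 8 base channels."""
        return cls(encoder_levels=3, base_channels=8, patch_shape=patch_shape)


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol.

    The full-scale defaults target real whole-body data (5 folds, 1000
    epochs, batch 2, SGD lr 1e-4, 128^3 crops); :meth:`desk` shrinks epochs
    and crop size and raises the learning rate (with heavy momentum) so the
    protocol converges at desk scale.
    """

    folds: int = 5
    epochs: int = 1000
    batch_size: int = 2
    learning_rate: float = 1e-4
    momentum: float = 0.99
    crop_shape: tuple[int, int, int] = (128, 128, 128)
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    @classmethod
    def desk(cls, folds: int = 2, epochs: int = 20,
             crop_shape: tuple[int, int, int] = (32, 32, 32), seed: int = 0) -> "TrainConfig":
        return cls(folds=folds, epochs=epochs, learning_rate=0.01, momentum=0.9,
                   crop_shape=crop_shape, seed=seed)


@dataclass
class ModelEnsemble:
    """Fold models fused by mean foreground probability, thresholded at 0.5.

    A mean probability of exactly 0.5 counts as foreground (the fixed tie
    rule that keeps runs bit-reproducible).
    """

    members: list
    config: UNetConfig
    threshold: float = 0.5
    normalize_global: tuple[float, float] | None = None  # optional (lo, hi) range

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")

    def foreground_probability(self, patch: np.ndarray) -> np.ndarray:
        x = self._normalize(patch)
        x, crop = _pad_to_divisor(x, 2 ** (self.config.encoder_levels - 1))
        probs = None
        for m in self.members:
            logits = m.forward(x[None], keep=False)
            p = softmax_fg(logits)[0]
            probs = p if probs is None else probs + p
        probs /= len(self.members)
        return probs[crop]

    def _normalize(self, patch: np.ndarray) -> np.ndarray:
        if self.normalize_global is not None:
            lo, hi = self.normalize_global
            if hi <= lo:
                return np.zeros_like(patch, dtype=np.float32)
            return np.clip((patch.astype(np.float32) - lo) / (hi - lo), 0.0, 1.0)
        return normalize_patch(patch)

    def predict(self, patch: np.ndarray) -> np.ndarray:
        return self.foreground_probability(patch) >= self.threshold


@dataclass
class ThresholdModel:
    """Stub model: fixed raw-intensity cutoff (no training, no normalization).

    Lets quantification, density and evaluation run without a trained
    network, and provides the exactness reference for tiled prediction:
    thresholding is purely voxel-local, so tiling with any grid must
    reproduce full-volume thresholding bit-exactly.
    """

    threshold: float

    def predict(self, patch: np.ndarray) -> np.ndarray:
        return np.asarray(patch) >= self.threshold


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Min-max normalize a patch to [0, 1]; constant patches map to zeros."""
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValueError("cannot normalize an empty patch")
    lo = float(patch.min())
    hi = float(patch.max())
    if hi == lo:
        return np.zeros_like(patch, dtype=np.float32)
    return ((patch.astype(np.float32) - lo) / (hi - lo)).astype(np.float32)


def build_model(config: UNetConfig, seed: int) -> UNet3D:
    """Initialize a U-Net per ``config``; parameters deterministic given seed."""
    return UNet3D(
        levels=config.encoder_levels,
        base_channels=config.base_channels,
        seed=seed,
        max_channels=config.max_channels,
        negative_slope=config.negative_slope,
    )


def _pad_to_divisor(x: np.ndarray, div: int):
    """Reflect-pad spatial dims up to a multiple of ``div``; return crop slices."""
    pads = []
    crops = []
    for d in x.shape:
        target = ((d + div - 1) // div) * div
        extra = target - d
        pads.append((0, extra))
        crops.append(slice(0, d))
    if any(p[1] for p in pads):
        x = np.pad(x, pads, mode="edge")
    return x, tuple(crops)


def _fold_split(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Deterministic partition of range(n) into ``folds`` validation sets."""
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def _random_crop(patch: np.ndarray, gt: np.ndarray, crop_shape, rng) -> tuple[np.ndarray, np.ndarray]:
    starts = [
        rng.integers(0, d - c + 1) if d > c else 0
        for d, c in zip(patch.shape, crop_shape)
    ]
    box = tuple(slice(int(s), int(s) + c) for s, c in zip(starts, crop_shape))
    return patch[box], gt[box]


def _augment(x: np.ndarray, y: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    # random flips on each axis, plus a random 90-degree rotation in the
    # lateral (y, x) plane; the axial direction is anisotropic and not mixed in
    for axis in range(3):
        if rng.integers(0, 2):
            x = np.flip(x, axis)
            y = np.flip(y, axis)
    k = int(rng.integers(0, 4))
    if k and x.shape[1] == x.shape[2]:
        x = np.rot90(x, k, axes=(1, 2))
        y = np.rot90(y, k, axes=(1, 2))
    return np.ascontiguousarray(x), np.ascontiguousarray(y)


def train(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    unet_cfg: UNetConfig,
    train_cfg: TrainConfig,
) -> tuple[ModelEnsemble, list[list[dict]]]:
    """K-fold training; returns the fold ensemble and per-fold epoch logs.

    Folds partition whole annotated patches (no subcrop ever crosses a fold
    boundary).  Per epoch, each training patch contributes one random crop;
    crops are normalized, optionally augmented, and batched.  Validation
    loss is computed on a deterministic center crop of each validation
    patch, and the lowest-validation-loss checkpoint is kept per fold.
    """
    if len(pairs) < train_cfg.folds:
        raise ValueError(
            f"need at least as many training pairs ({len(pairs)}) as folds ({train_cfg.folds})"
        )
    for _, gt in pairs:
        vals = np.unique(gt)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("ground-truth patches must be binary")

    master = np.random.default_rng(train_cfg.seed)
    fold_sets = _fold_split(len(pairs), train_cfg.folds, master)
    model_seeds = np.random.SeedSequence(train_cfg.seed).generate_state(
        train_cfg.folds, dtype=np.uint32
    )

    crop = train_cfg.crop_shape
    members = []
    logs: list[list[dict]] = []
    for fold, val_idx in enumerate(fold_sets):
        val_idx = set(int(i) for i in val_idx)
        train_idx = [i for i in range(len(pairs)) if i not in val_idx]
        rng = np.random.default_rng(int(model_seeds[fold]))
        model = build_model(unet_cfg, int(model_seeds[fold]))
        opt = SGD(model.parameters(), lr=train_cfg.learning_rate, momentum=train_cfg.momentum)

        # deterministic center-crop validation set, normalized once
        val_batches = []
        for i in sorted(val_idx):
            patch, gt = pairs[i]
            box = tuple(
                slice((d - c) // 2, (d - c) // 2 + c) for d, c in zip(patch.shape, crop)
            )
            val_batches.append(
                (normalize_patch(patch[box]), gt[box].astype(np.float32))
            )

        best_loss = np.inf
        best_state = model.get_state()
        fold_log = []
        for epoch in range(train_cfg.epochs):
            order = rng.permutation(len(train_idx))
            epoch_loss = 0.0
            n_steps = 0
            batch_x, batch_y = [], []
            for j in order:
                patch, gt = pairs[train_idx[int(j)]]
                x, y = _random_crop(patch, gt, crop, rng)
                x = normalize_patch(x)
                y = y.astype(np.float32)
                if train_cfg.augment:
                    x, y = _augment(x, y, rng)
                batch_x.append(x)
                batch_y.append(y)
                if len(batch_x) == train_cfg.batch_size:
                    epoch_loss += _train_step(model, opt, batch_x, batch_y)
                    n_steps += 1
                    batch_x, batch_y = [], []
            if batch_x:
                epoch_loss += _train_step(model, opt, batch_x, batch_y)
                n_steps += 1

            val_loss = 0.0
            for x, y in val_batches:
                logits = model.forward(x[None], keep=False)
                loss, _, _, _ = dice_ce_loss_and_grad(logits, y[None])
                val_loss += loss
            val_loss /= max(1, len(val_batches))
            fold_log.append(
                {"epoch": epoch, "train_loss": epoch_loss / max(1, n_steps),
                 "val_loss": val_loss}
            )
            if val_loss < best_loss:
                best_loss = val_loss
                best_state = model.get_state()
        model.set_state(best_state)
        members.append(model)
        logs.append(fold_log)

    return ModelEnsemble(members=members, config=unet_cfg), logs


def _train_step(model: UNet3D, opt: SGD, batch_x, batch_y) -> float:
    x = np.stack(batch_x)[:, None]
    y = np.stack(batch_y)
    opt.zero_grad()
    logits = model.forward(x)
    loss, _, _, glogits = dice_ce_loss_and_grad(logits, y)
    model.backward(glogits)
    opt.step()
    return loss


def predict_patch(model, patch: np.ndarray) -> np.ndarray:
    """Binary mask for one patch (ensemble or any object with ``predict``)."""
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValueError("cannot predict on an empty patch")
    return np.asarray(model.predict(patch), dtype=bool)


def predict_volume(model, volume: VoxelGrid | np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Tile-wise prediction over a full volume, stitched to volume shape.

    Tiles are read with their halo, predicted independently, and stitched;
    the result does not depend on tile order.  ``volume`` may be any
    3D-indexable array (in-memory or chunked storage).
    """
    data = volume.data if isinstance(volume, VoxelGrid) else volume
    shape = tuple(int(s) for s in data.shape)
    if tuple(grid.volume_shape) != shape:
        raise ValueError(f"grid shape {grid.volume_shape} != volume shape {shape}")
    outputs = []
    for spec in grid.patches:
        tile = np.asarray(data[spec.read_slices(shape)])
        outputs.append((spec, predict_patch(model, tile)))
    return stitch(outputs, grid)
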