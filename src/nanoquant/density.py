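"""Smoothed full-resolution contrast-density maps.

For whole-body visualisation, per-voxel background-relative contrast on the
segmented foreground is pooled over local windows (default 16 x 16 voxels
laterally by 4 axially, matching the coarser axial sampling) and then
smoothed with a 3D Gaussian, yielding a full-resolution density map whose
local level tracks the amount of delivered nanocarrier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .quantify import BackgroundTable, WHOLE_VOLUME, _check_binary
from .volume_io import LabelVolume, VoxelGrid

__all__ = ["DensityConfig", "contrast_volume", "block_density", "smooth_density"]


@dataclass
class DensityConfig:
    """Windowing and smoothing parameters for the density map.

    ``window`` is in (z, y, x) voxels; the default (4, 16, 16) places the
    small extent along the axial direction.  With ``stride`` equal to
    ``window`` (the default) the volume is partitioned into blocks and every
    voxel of a block is assigned the block's contrast sum; with a smaller
    stride a moving-sum (box-filter) reading is used instead.  ``gaussian_sigma``
    defaults to half the window per axis; sigma below half a voxel on every
    axis makes smoothing the identity.
    """

    window: tuple[int, int, int] = (4, 16, 16)
    stride: tuple[int, int, int] | None = None  # None -> block mode (stride = window)
    gaussian_sigma: tuple[float, float, float] | None = None  # None -> window / 2
    boundary: str = "wrap"  # {"wrap", "reflect", "constant"}

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.window):
            raise ValueError(f"window entries must be >= 1, got {self.window}")
        if self.stride is not None and any(s < 1 for s in self.stride):
            raise ValueError(f"stride entries must be >= 1, got {self.stride}")
        if self.gaussian_sigma is not None and any(s <= 0 for s in self.gaussian_sigma):
            raise ValueError(f"gaussian_sigma must be > 0, got {self.gaussian_sigma}")
        if self.boundary not in ("wrap", "reflect", "constant"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")

    @property
    def sigma(self) -> tuple[float, float, float]:
        if self.gaussian_sigma is not None:
            return self.gaussian_sigma
        return tuple(w / 2.0 for w in self.window)


def contrast_volume(
    volume: VoxelGrid | np.ndarray,
    organs: LabelVolume,
    mask: np.ndarray,
    backgrounds: BackgroundTable,
    instance_organs: tuple[np.ndarray, dict[int, int]] | None = None,
) -> np.ndarray:
    """Voxelwise background-relative contrast on the segmented foreground.

    c_v = max(0, (I_v - B_o(v)) / B_o(v)) on mask-foreground voxels, 0
    elsewhere, where o(v) is the voxel's organ (label 0 uses the
    whole-volume background).

    ``instance_organs`` optionally supplies ``(instance_labels, {instance ->
    organ})`` so every voxel of an instance is scored against its instance's
    assigned organ background; the field then sums exactly to the instance
    table's total contrast even when instances straddle organ borders.
    """
    data = volume.data if isinstance(volume, VoxelGrid) else np.asarray(volume)
    labels = organs.labels
    mask = _check_binary(mask)
    if not (data.shape == labels.shape == mask.shape):
        raise ValueError("volume, organ labels and mask must share a shape")
    if instance_organs is not None:
        inst, assign = instance_organs
        if inst.shape != data.shape:
            raise ValueError("instance labels and volume shapes differ")
        organ_of = np.zeros(int(inst.max()) + 1, dtype=np.int64)
        for instance_id, organ in assign.items():
            organ_of[int(instance_id)] = int(organ)
        labels = organ_of[inst]
    max_label = int(labels.max())
    lut = np.empty(max_label + 1, dtype=np.float64)
    lut[:] = backgrounds[WHOLE_VOLUME]
    for organ, b in backgrounds.background.items():
        if 0 <= organ <= max_label:
            lut[organ] = b
    b_map = lut[labels]
    c = np.zeros(data.shape, dtype=np.float64)
    fg = mask
    c[fg] = np.maximum(0.0, (data[fg].astype(np.float64) - b_map[fg]) / b_map[fg])
    return c


def block_density(contrast: np.ndarray, config: DensityConfig) -> np.ndarray:
    """Pool contrast over windows; every voxel gets its window's sum.

    Block mode (stride = window): the volume is partitioned into blocks
    (remainder blocks clipped at the far edge) and each block's sum is
    broadcast to all of its voxels.  Moving-sum mode (stride < window):
    each voxel gets the sum over the window centred on it (box filter with
    the configured boundary mode).
    """
    contrast = np.asarray(contrast, dtype=np.float64)
    if any(w > d for w, d in zip(config.window, contrast.shape)):
        raise ValueError(
            f"window {config.window} larger than volume {contrast.shape} on some axis"
        )
    stride = config.stride if config.stride is not None else config.window
    if tuple(stride) == tuple(config.window):
        out = contrast
        for axis, w in enumerate(config.window):
            d = out.shape[axis]
            edges = np.arange(0, d, w)
            sums = np.add.reduceat(out, edges, axis=axis)
            block_sizes = np.diff(np.append(edges, d))
            out = np.repeat(sums, block_sizes, axis=axis)
        return out
    mode = {"wrap": "wrap", "reflect": "reflect", "constant": "constant"}[config.boundary]
    return ndimage.uniform_filter(contrast, size=config.window, mode=mode) * float(
        np.prod(config.window)
    )


def smooth_density(raw: np.ndarray, config: DensityConfig) -> np.ndarray:
    """Gaussian-smooth the pooled density (unit-sum kernel, shape preserved)."""
    raw = np.asarray(raw, dtype=np.float64)
    sigma = config.sigma
    if all(s < 0.5 for s in sigma):
        return raw.copy()
    mode = {"wrap": "wrap", "reflect": "reflect", "constant": "constant"}[config.boundary]
    return ndimage.gaussian_filter(raw, sigma=sigma, mode=mode)
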