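"""Volume I/O and the tiling/stitching layer.

Whole-body light-sheet scans can reach tens of billions of voxels
(a single mouse scan may span ~30,000 x 10,500 x 2,000 voxels), far beyond
what fits in memory at once.  This module provides

* :class:`VoxelGrid` / :class:`LabelVolume` — the in-memory containers for
  intensity volumes and organ label maps, in fixed (z, y, x) axis order;
* reading/writing multi-page TIFF, directories of TIFF slices, and NIfTI-1;
* :func:`plan_tiles` / :func:`stitch` — an exact partition of a volume into
  core tiles (default cap 500^3 voxels) with an optional halo of read-only
  context, so that any per-patch operator can be applied at scale and the
  results reassembled with every voxel written exactly once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "LabelVolume",
    "PatchSpec",
    "PatchGrid",
    "read_volume",
    "write_volume",
    "plan_tiles",
    "stitch",
    "read_organ_names",
    "write_organ_names",
]

#: default physical voxel size in micrometres, (z, y, x): 6 um axial step,
#: ~1.7 um lateral sampling typical of whole-body light-sheet acquisitions.
DEFAULT_SPACING = (6.0, 1.7, 1.7)

#: inference tile cap used for whole-body volumes.
DEFAULT_MAX_PATCH = (500, 500, 500)


@dataclass
class VoxelGrid:
    """A 3D scalar intensity volume with anisotropic voxel spacing.

    ``data`` is indexed (z, y, x); ``spacing`` gives the physical voxel
    size per axis in micrometres, same order.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer organ-label volume aligned to a :class:`VoxelGrid`.

    Label 0 is reserved for "outside any organ"; every nonzero label that
    occurs in ``labels`` must have an entry in ``names``.
    """

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer, got dtype={self.labels.dtype}")
        self.names = {int(k): str(v) for k, v in self.names.items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels present in volume but missing from names: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def check_aligned(self, grid: VoxelGrid) -> None:
        if self.labels.shape != grid.data.shape:
            raise ValueError(
                f"label volume shape {self.labels.shape} does not match "
                f"intensity volume shape {grid.data.shape}"
            )


@dataclass(frozen=True)
class PatchSpec:
    """One tile of a volume: a core region plus a halo of read-only context.

    ``origin`` and ``core_shape`` define the half-open core block
    ``[origin, origin + core_shape)``.  At read time the block is expanded
    by ``halo`` per axis (clipped at the volume boundary); at write time the
    halo is cropped again so cores tile the volume exactly.
    """

    origin: tuple[int, int, int]
    core_shape: tuple[int, int, int]
    halo: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if any(h < 0 for h in self.halo):
            raise ValueError(f"halo must be >= 0 per axis, got {self.halo}")
        if any(c < 1 for c in self.core_shape):
            raise ValueError(f"core_shape must be >= 1 per axis, got {self.core_shape}")

    def core_slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + c) for o, c in zip(self.origin, self.core_shape))

    def read_bounds(self, volume_shape: Sequence[int]) -> tuple[tuple[int, int], ...]:
        """Halo-expanded [start, stop) per axis, clipped to the volume."""
        return tuple(
            (max(0, o - h), min(int(d), o + c + h))
            for o, c, h, d in zip(self.origin, self.core_shape, self.halo, volume_shape)
        )

    def read_slices(self, volume_shape: Sequence[int]) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in self.read_bounds(volume_shape))

    def read_shape(self, volume_shape: Sequence[int]) -> tuple[int, int, int]:
        return tuple(b - a for a, b in self.read_bounds(volume_shape))

    def crop_slices(self, volume_shape: Sequence[int]) -> tuple[slice, slice, slice]:
        """Slices that cut the core region out of the halo-expanded read block."""
        out = []
        for (a, _b), o, c in zip(self.read_bounds(volume_shape), self.origin, self.core_shape):
            lo = o - a
            out.append(slice(lo, lo + c))
        return tuple(out)


@dataclass
class PatchGrid:
    """An exact tiling of a volume into disjoint, covering core regions."""

    volume_shape: tuple[int, int, int]
    max_patch_shape: tuple[int, int, int]
    halo: tuple[int, int, int]
    patches: list[PatchSpec]

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)


def plan_tiles(
    volume_shape: Sequence[int],
    max_patch_shape: Sequence[int] = DEFAULT_MAX_PATCH,
    halo: Sequence[int] = (0, 0, 0),
) -> PatchGrid:
    """Partition ``volume_shape`` into core tiles of at most ``max_patch_shape``.

    Per axis the number of tiles is ``ceil(dim / max_patch)``; all tiles take
    the full ``max_patch`` extent except the last one per axis, which takes
    the remainder.  Halo is context added at read time only and never affects
    the partition.
    """
    volume_shape = tuple(int(d) for d in volume_shape)
    max_patch_shape = tuple(int(m) for m in max_patch_shape)
    halo = tuple(int(h) for h in halo)
    if any(d < 1 for d in volume_shape):
        raise ValueError(f"volume dimensions must be >= 1, got {volume_shape}")
    if any(m < 1 for m in max_patch_shape):
        raise ValueError(f"max_patch_shape entries must be >= 1, got {max_patch_shape}")
    if any(h < 0 for h in halo):
        raise ValueError(f"halo must be >= 0, got {halo}")

    per_axis_starts = []
    for d, m in zip(volume_shape, max_patch_shape):
        starts = list(range(0, d, m))
        per_axis_starts.append(starts)

    patches = []
    for z0 in per_axis_starts[0]:
        for y0 in per_axis_starts[1]:
            for x0 in per_axis_starts[2]:
                core = tuple(
                    min(m, d - o)
                    for o, m, d in zip((z0, y0, x0), max_patch_shape, volume_shape)
                )
                patches.append(PatchSpec((z0, y0, x0), core, halo))
    return PatchGrid(volume_shape, max_patch_shape, halo, patches)


def stitch(
    patch_outputs: Sequence[tuple[PatchSpec, np.ndarray]],
    grid: PatchGrid,
) -> np.ndarray:
    """Reassemble per-patch outputs into a full volume.

    Each output must have the halo-expanded read shape of its spec; the halo
    is cropped and the core written into place.  Every voxel of the result is
    written exactly once; the result is independent of patch order.
    """
    expected = {p.origin: p for p in grid.patches}
    seen = set()
    out = None
    for spec, arr in patch_outputs:
        arr = np.asarray(arr)
        if spec.origin not in expected:
            raise ValueError(f"patch at origin {spec.origin} not part of the grid")
        want = spec.read_shape(grid.volume_shape)
        if tuple(arr.shape) != tuple(want):
            raise ValueError(
                f"patch at origin {spec.origin}: output shape {arr.shape} != "
                f"expected halo-expanded shape {want}"
            )
        if out is None:
            out = np.zeros(grid.volume_shape, dtype=arr.dtype)
        core = arr[spec.crop_slices(grid.volume_shape)]
        out[spec.core_slices()] = core
        seen.add(spec.origin)
    missing = set(expected) - seen
    if missing:
        raise ValueError(f"missing outputs for {len(missing)} patches, e.g. {sorted(missing)[:3]}")
    return out


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff"}
_NIFTI_SUFFIXES = {".nii"}


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "tiff_stack"
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] in _TIFF_SUFFIXES:
        return "tiff_stack"
    if suffixes and (suffixes[-1] in _NIFTI_SUFFIXES or suffixes[-2:] == [".nii", ".gz"]):
        return "nifti"
    raise ValueError(f"cannot infer volume format from path {path}")


def read_volume(
    path,
    format: str | None = None,
    spacing: Sequence[float] | None = None,
) -> VoxelGrid:
    """Read a 3D volume as a :class:`VoxelGrid` in (z, y, x) order.

    ``format`` is ``"tiff_stack"`` (multi-page TIFF or a directory of TIFF
    slices, lexicographic slice order = ascending z) or ``"nifti"``; when
    omitted it is inferred from the path.  Spacing is taken from file
    metadata when the format records it (NIfTI), else from the ``spacing``
    argument, else the light-sheet default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume path does not exist: {path}")
    fmt = format or _infer_format(path)

    if fmt == "tiff_stack":
        import tifffile

        if path.is_dir():
            slices = sorted(
                p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES
            )
            if not slices:
                raise FileNotFoundError(f"no TIFF slices found in directory {path}")
            planes = [tifffile.imread(p) for p in slices]
            shapes = {p.shape for p in planes}
            if len(shapes) != 1:
                raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
            if planes[0].ndim != 2:
                raise ValueError(f"slices in {path} are not 2D (shape {planes[0].shape})")
            data = np.stack(planes, axis=0)
        else:
            data = tifffile.imread(path)
            if data.ndim == 2:
                raise ValueError(f"{path} holds a single 2D image, not a 3D volume")
            if data.ndim != 3:
                raise ValueError(f"{path} decodes to ndim={data.ndim}, expected 3")
        return VoxelGrid(data, tuple(spacing) if spacing else DEFAULT_SPACING)

    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"{path} decodes to ndim={data.ndim}, expected 3")
        # NIfTI stores (x, y, z); transpose to (z, y, x).
        data = np.transpose(data, (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        if spacing is not None:
            sp = tuple(spacing)
        elif all(z > 0 for z in zooms):
            sp = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        else:
            sp = DEFAULT_SPACING
        return VoxelGrid(np.ascontiguousarray(data), sp)

    raise ValueError(f"unknown format {fmt!r}")


def write_volume(grid, path, format: str | None = None) -> None:
    """Write a volume (``VoxelGrid``, ``LabelVolume`` or bare 3D array).

    Integer data round-trips bit-identically through :func:`read_volume`;
    float32 data round-trips losslessly through both formats.
    """
    path = Path(path)
    if isinstance(grid, VoxelGrid):
        data, spacing = grid.data, grid.spacing
    elif isinstance(grid, LabelVolume):
        data, spacing = grid.labels, DEFAULT_SPACING
    else:
        data, spacing = np.asarray(grid), DEFAULT_SPACING
    if data.ndim != 3:
        raise ValueError(f"can only write 3D volumes, got ndim={data.ndim}")
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    if fmt == "tiff_stack":
        import tifffile

        if data.dtype == bool:
            data = data.astype(np.uint8)
        tifffile.imwrite(path, data, photometric="minisblack")
        return
    if fmt == "nifti":
        import nibabel as nib

        if data.dtype == bool:
            data = data.astype(np.uint8)
        affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
        img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
        img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
        nib.save(img, str(path))
        return
    raise ValueError(f"unknown format {fmt!r}")


def read_organ_names(path) -> dict[int, str]:
    """Read the organ-name sidecar, a JSON object mapping label -> name."""
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): str(v) for k, v in raw.items()}


def write_organ_names(names: dict[int, str], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({str(int(k)): str(v) for k, v in names.items()}, fh, indent=2, sort_keys=True)
        fh.write("\n")
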