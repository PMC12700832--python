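"""Synthetic whole-body phantom generator.

Real inputs to the pipeline are cleared-mouse light-sheet volumes: organ
compartments with distinct autofluorescence backgrounds, sprinkled with
bright blob-shaped delivery events (nanocarrier uptake by cells or cell
clusters).  The phantom emulates exactly those features with full ground
truth so every downstream stage — segmentation, quantification, density
mapping, evaluation — is testable without any real data:

* organ compartments are ellipsoids with per-organ background levels;
* delivery events are anisotropic Gaussian blobs (fine lateral, coarse
  axial, matching the ~1.7 um lateral / 6 um axial sampling);
* the ground-truth footprint of a blob is the set of voxels where its
  noiseless contribution reaches at least half of its peak amplitude;
  overlapping footprints merge into one ground-truth instance, mirroring
  how the real pipeline treats touching targeted cells as one cluster;
* all randomness flows from a single seed through named generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .volume_io import DEFAULT_SPACING, LabelVolume, VoxelGrid

__all__ = [
    "OrganSpec",
    "ParticleTruth",
    "PhantomConfig",
    "PhantomSample",
    "default_organs",
    "generate_phantom",
    "render_blob",
    "make_training_set",
    "planted_contrast_by_organ",
]


@dataclass(frozen=True)
class OrganSpec:
    """One ellipsoidal organ compartment."""

    label: int
    name: str
    center: tuple[float, float, float]  # (z, y, x) voxels
    semi_axes: tuple[float, float, float]  # (z, y, x) voxels


@dataclass(frozen=True)
class ParticleTruth:
    """Ground truth for one planted delivery event."""

    id: int
    center: tuple[float, float, float]
    radius: tuple[float, float, float]  # Gaussian sigma per axis (z, y, x)
    amplitude: float
    organ: int

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if any(r <= 0 for r in self.radius):
            raise ValueError("radius (sigma) must be > 0 per axis")


def default_organs(shape: tuple[int, int, int]) -> list[OrganSpec]:
    """Three disjoint ellipsoidal organs scaled to the volume shape."""
    z, y, x = shape
    return [
        OrganSpec(1, "liver", (0.50 * z, 0.32 * y, 0.30 * x), (0.38 * z, 0.24 * y, 0.22 * x)),
        OrganSpec(2, "spleen", (0.50 * z, 0.32 * y, 0.74 * x), (0.34 * z, 0.20 * y, 0.18 * x)),
        OrganSpec(3, "kidney", (0.50 * z, 0.75 * y, 0.52 * x), (0.34 * z, 0.17 * y, 0.28 * x)),
    ]


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic volume.

    Defaults describe a high signal-to-noise acquisition: organ
    autofluorescence backgrounds of 80-150 intensity units over a dim
    body cavity, blob peak amplitudes 4-10x background drawn log-uniformly,
    and additive Gaussian read noise well below the blob amplitudes.
    """

    shape: tuple[int, int, int] = (64, 96, 96)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    organs: list[OrganSpec] | None = None  # None -> default_organs(shape)
    outside_background: float = 30.0
    background: dict[int, float] = field(
        default_factory=lambda: {1: 120.0, 2: 80.0, 3: 150.0}
    )
    noise_sigma: float = 5.0
    poisson_scale: float = 0.0  # adds sqrt(signal)*scale to the local noise sd
    particles_per_organ: dict[int, int] | int = 12
    amplitude_range: tuple[float, float] = (400.0, 1200.0)  # log-uniform
    sigma_lateral_range: tuple[float, float] = (2.0, 4.0)  # voxels, y and x
    sigma_axial_range: tuple[float, float] = (0.9, 1.6)  # voxels, z
    footprint_threshold: float = 0.5  # fraction of amplitude defining GT support
    dtype: str = "float32"

    def resolved_organs(self) -> list[OrganSpec]:
        organs = self.organs if self.organs is not None else default_organs(self.shape)
        labels = [o.label for o in organs]
        if len(set(labels)) != len(labels):
            raise ValueError("organ labels must be unique")
        return organs

    def particle_count(self, label: int) -> int:
        if isinstance(self.particles_per_organ, dict):
            return int(self.particles_per_organ.get(label, 0))
        return int(self.particles_per_organ)

    def validate(self) -> None:
        if any(d < 1 for d in self.shape):
            raise ValueError(f"shape entries must be >= 1, got {self.shape}")
        for lo, hi in (self.amplitude_range, self.sigma_lateral_range, self.sigma_axial_range):
            if not (0 < lo <= hi):
                raise ValueError("distribution bounds must be positive and ordered")
        if not (0 < self.footprint_threshold < 1):
            raise ValueError("footprint_threshold must lie in (0, 1)")
        for o in self.resolved_organs():
            for c, a, d in zip(o.center, o.semi_axes, self.shape):
                if c - a < -0.5 or c + a > d - 0.5:
                    raise ValueError(f"organ {o.name!r} ellipsoid exceeds the volume bounds")


@dataclass
class PhantomSample:
    """A synthetic volume plus everything needed to score a pipeline run."""

    volume: VoxelGrid
    organs: LabelVolume
    gt_instances: np.ndarray  # int32 instance labels, 0 = background
    truth: pd.DataFrame  # columns id, z, y, x, sigma_z/y/x, amplitude, organ, instance_id
    config: PhantomConfig


def paint_organs(config: PhantomConfig) -> LabelVolume:
    labels = np.zeros(config.shape, dtype=np.int32)
    zz, yy, xx = np.meshgrid(*(np.arange(d) for d in config.shape), indexing="ij")
    names = {}
    for organ in config.resolved_organs():
        cz, cy, cx = organ.center
        az, ay, ax = organ.semi_axes
        inside = (
            ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
        ) <= 1.0
        labels[inside] = organ.label
        names[organ.label] = organ.name
    return LabelVolume(labels, names)


def render_blob(
    center: tuple[float, float, float],
    radius: tuple[float, float, float],
    amplitude: float,
    shape: tuple[int, int, int],
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Render one anisotropic Gaussian blob, truncated at 3 sigma per axis.

    Returns a bounding-box slice tuple and the dense contribution inside it.
    The field is scaled so the voxel nearest the centre carries exactly
    ``amplitude`` (for integer centres this is the plain Gaussian).
    """
    if any(r <= 0 for r in radius):
        raise ValueError("radius (sigma) must be > 0 per axis")
    for c, d in zip(center, shape):
        if not (-0.5 <= c <= d - 0.5):
            raise ValueError(f"blob centre {center} outside volume of shape {shape}")
    los, his, axes = [], [], []
    for c, r, d in zip(center, radius, shape):
        lo = max(0, int(np.floor(c - 3 * r)))
        hi = min(d, int(np.ceil(c + 3 * r)) + 1)
        los.append(lo)
        his.append(hi)
        axes.append(np.arange(lo, hi, dtype=np.float64))
    if amplitude == 0:
        box = tuple(slice(lo, hi) for lo, hi in zip(los, his))
        return box, np.zeros([hi - lo for lo, hi in zip(los, his)], dtype=np.float32)
    gz = np.exp(-((axes[0] - center[0]) ** 2) / (2 * radius[0] ** 2))
    gy = np.exp(-((axes[1] - center[1]) ** 2) / (2 * radius[1] ** 2))
    gx = np.exp(-((axes[2] - center[2]) ** 2) / (2 * radius[2] ** 2))
    blob = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    blob *= amplitude / blob.max()
    box = tuple(slice(lo, hi) for lo, hi in zip(los, his))
    return box, blob.astype(np.float32)


def _relabel_scan_order(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels to 1..K by first-voxel scan order."""
    flat = labels.ravel()
    nz = np.flatnonzero(flat)
    if nz.size == 0:
        return labels
    vals, first = np.unique(flat[nz], return_index=True)
    order = np.argsort(nz[first], kind="stable")
    lut = np.zeros(int(vals.max()) + 1, dtype=labels.dtype)
    lut[vals[order]] = np.arange(1, len(vals) + 1, dtype=labels.dtype)
    return lut[labels]


def generate_phantom(config: PhantomConfig, seed: int) -> PhantomSample:
    """Generate one phantom: organs + blobs + noise, with full ground truth.

    Deterministic given ``(config, seed)``.  Particle centres are sampled
    uniformly over the interior voxels of their assigned organ (with
    sub-voxel jitter that keeps the centre inside the sampled voxel).
    """
    from scipy import ndimage

    config.validate()
    rng = np.random.default_rng(seed)
    organs = paint_organs(config)
    labels = organs.labels

    background = np.full(config.shape, config.outside_background, dtype=np.float64)
    for organ in config.resolved_organs():
        level = config.background.get(organ.label)
        if level is None:
            raise ValueError(f"no background level configured for organ {organ.label}")
        background[labels == organ.label] = level

    signal = np.zeros(config.shape, dtype=np.float64)
    footprint = np.zeros(config.shape, dtype=bool)
    records = []
    pid = 0
    for organ in config.resolved_organs():
        n = config.particle_count(organ.label)
        if n == 0:
            continue
        interior = np.flatnonzero(labels == organ.label)
        if interior.size == 0:
            raise ValueError(
                f"organ {organ.name!r} has no interior voxels but {n} particles requested"
            )
        picks = rng.choice(interior, size=n, replace=False if n <= interior.size else True)
        coords = np.column_stack(np.unravel_index(picks, config.shape)).astype(np.float64)
        coords += rng.uniform(-0.49, 0.49, size=coords.shape)
        lo_a, hi_a = config.amplitude_range
        amplitudes = np.exp(rng.uniform(np.log(lo_a), np.log(hi_a), size=n))
        sig_lat = rng.uniform(*config.sigma_lateral_range, size=(n, 2))
        sig_ax = rng.uniform(*config.sigma_axial_range, size=n)
        for k in range(n):
            center = tuple(coords[k])
            radius = (float(sig_ax[k]), float(sig_lat[k, 0]), float(sig_lat[k, 1]))
            amp = float(amplitudes[k])
            box, blob = render_blob(center, radius, amp, config.shape)
            signal[box] += blob
            footprint[box] |= blob >= config.footprint_threshold * amp
            pid += 1
            records.append(
                ParticleTruth(pid, center, radius, amp, int(organ.label))
            )

    gt, _ = ndimage.label(footprint, structure=np.ones((3, 3, 3), dtype=bool))
    gt = _relabel_scan_order(gt.astype(np.int32))

    noise_sd = config.noise_sigma + config.poisson_scale * np.sqrt(np.maximum(signal, 0.0))
    noiseless = background + signal
    data = noiseless + rng.standard_normal(config.shape) * noise_sd
    data = np.clip(data, 0.0, None)
    dtype = np.dtype(config.dtype)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        data = np.clip(np.rint(data), info.min, info.max)
    data = data.astype(dtype)

    rows = []
    for r in records:
        cz, cy, cx = (int(round(c)) for c in r.center)
        rows.append(
            dict(
                id=r.id,
                z=r.center[0], y=r.center[1], x=r.center[2],
                sigma_z=r.radius[0], sigma_y=r.radius[1], sigma_x=r.radius[2],
                amplitude=r.amplitude,
                organ=r.organ,
                instance_id=int(gt[cz, cy, cx]),
            )
        )
    truth = pd.DataFrame(
        rows,
        columns=["id", "z", "y", "x", "sigma_z", "sigma_y", "sigma_x",
                 "amplitude", "organ", "instance_id"],
    )

    return PhantomSample(
        volume=VoxelGrid(data, config.spacing),
        organs=organs,
        gt_instances=gt,
        truth=truth,
        config=config,
    )


def planted_contrast_by_organ(sample: PhantomSample) -> dict[int, float]:
    """Analytic total background-relative contrast per organ.

    For each planted blob, sums (noiseless contribution / organ background)
    over the blob's ground-truth footprint voxels — what a perfect
    segmentation of the footprints would measure in the absence of noise.
    Used as the oracle for quantification-recovery checks.
    """
    config = sample.config
    totals: dict[int, float] = {}
    for r in sample.truth.itertuples():
        center = (r.z, r.y, r.x)
        radius = (r.sigma_z, r.sigma_y, r.sigma_x)
        box, blob = render_blob(center, radius, r.amplitude, config.shape)
        fp = blob >= config.footprint_threshold * r.amplitude
        level = config.background.get(int(r.organ), config.outside_background)
        totals[int(r.organ)] = totals.get(int(r.organ), 0.0) + float(blob[fp].sum()) / level
    return totals


def make_training_set(
    config: PhantomConfig,
    n_patches: int,
    patch_shape: tuple[int, int, int],
    seed: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Crop (intensity, binary ground truth) training pairs from fresh phantoms.

    Each patch comes from its own freshly generated phantom, cropped around a
    random organ-interior voxel (clipped to the volume bounds), so patches
    sample diverse organ backgrounds.  Deterministic given ``seed``.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    if any(p > d for p, d in zip(patch_shape, config.shape)):
        raise ValueError(f"patch_shape {patch_shape} does not fit in volume {config.shape}")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_patches, dtype=np.uint32)
    pairs = []
    for i in range(n_patches):
        sample = generate_phantom(config, int(child_seeds[2 * i]))
        rng = np.random.default_rng(int(child_seeds[2 * i + 1]))
        organ_voxels = np.flatnonzero(sample.organs.labels > 0)
        pick = int(rng.choice(organ_voxels))
        center = np.unravel_index(pick, config.shape)
        starts = [
            int(np.clip(c - p // 2, 0, d - p))
            for c, p, d in zip(center, patch_shape, config.shape)
        ]
        box = tuple(slice(s, s + p) for s, p in zip(starts, patch_shape))
        intensity = np.ascontiguousarray(sample.volume.data[box])
        gt = np.ascontiguousarray((sample.gt_instances[box] > 0).astype(np.uint8))
        pairs.append((intensity, gt))
    return pairs
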