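"""Synthetic spine phantoms with known ground truth.

The phantom emulates the gross geometry of a lumbar-spine MR slice or
volume: a column of bright vertebral bodies (axis-aligned
super-ellipsoids stacked along the first array axis) separated by
lower-intensity disc bands, plus a tubular vessel running parallel to
the column, on a dark background. Tissue intensities are piecewise
constant, with optional additive Gaussian noise, so every structure has
an exact label mask and every vertebral body a known centroid landmark.

Ground-truth deformations are drawn from the package's own
:class:`~spinereg.bspline.BSplineTransform` model (uniform control-point
displacements), so registration experiments can score recovery against a
transform that is representable exactly.

All randomness is reproducible: each operation derives its own RNG
stream from ``(seed, operation tag)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bspline import BSplineTransform
from .exceptions import ConfigError
from .io import ImageVolume, LabelMask, LandmarkSet

__all__ = ["PhantomConfig", "generate_phantom", "random_deformation",
           "add_noise", "segmentation_dataset"]

DEFAULT_INTENSITIES = {
    "background": 20.0,
    "vertebra": 200.0,
    "disc": 120.0,
    "vessel": 160.0,
}

# RNG stream tags, one per randomized operation
_STREAM_NOISE = 1
_STREAM_DEFORM = 2
_STREAM_DATASET = 3


@dataclass
class PhantomConfig:
    """Geometry, contrast and noise settings for a synthetic spine phantom.

    Defaults give a 64x64 2D sagittal-like slice with the five lumbar
    vertebral bodies, 1 mm voxels, and noise-free tissue intensities.
    """

    shape: tuple[int, ...] = (64, 64)
    n_vertebrae: int = 5
    vessel_radius: float = 2.0
    intensity_levels: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES))
    noise_sd: float = 0.0
    seed: int = 0
    spacing: tuple[float, ...] | float = 1.0

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.shape) not in (2, 3):
            raise ConfigError("shape must be 2D or 3D")
        if self.n_vertebrae < 1:
            raise ConfigError("n_vertebrae must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.vessel_radius <= 0:
            raise ConfigError("vessel_radius must be > 0")
        levels = dict(DEFAULT_INTENSITIES)
        levels.update(self.intensity_levels or {})
        self.intensity_levels = levels
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing),) * len(self.shape)
        else:
            self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def ndim(self) -> int:
        return len(self.shape)


def _geometry(config: PhantomConfig):
    """Voxel-space centers and radii of the phantom structures."""
    shape = np.asarray(config.shape, dtype=np.float64)
    n = config.n_vertebrae
    L0 = shape[0]
    slot = L0 / n                     # axial slot per vertebra
    body_rz = 0.35 * slot             # body half-height
    disc_rz = max(1.0, 0.10 * slot)   # disc band half-height
    if body_rz < 1.5:
        raise ConfigError(
            f"shape {config.shape} too small along the stacking axis for "
            f"{n} vertebrae")
    if config.ndim == 2:
        Lx = shape[1]
        cx, rx = 0.45 * (Lx - 1), 0.28 * Lx
        vx = 0.84 * (Lx - 1)
        plane_centers, plane_radii = (cx,), (rx,)
        vessel_center = (vx,)
    else:
        Ly, Lx = shape[1], shape[2]
        cy, ry = 0.45 * (Ly - 1), 0.28 * Ly
        cx, rx = 0.50 * (Lx - 1), 0.30 * Lx
        vy = 0.85 * (Ly - 1)
        plane_centers, plane_radii = (cy, cx), (ry, rx)
        vessel_center = (vy, 0.50 * (Lx - 1))
    if min(plane_radii) < 2.0:
        raise ConfigError(f"shape {config.shape} too small in-plane")
    # the vessel must clear the vertebral column
    gap = vessel_center[0] - config.vessel_radius - (
        plane_centers[0] + plane_radii[0])
    if gap < 0.5:
        raise ConfigError(
            f"shape {config.shape} leaves no room for the vessel "
            f"(clearance {gap:.2f} voxels)")
    centers0 = (np.arange(n) + 0.5) * slot
    return centers0, body_rz, disc_rz, plane_centers, plane_radii, \
        vessel_center


def generate_phantom(config: PhantomConfig
                     ) -> tuple[ImageVolume, LabelMask, LandmarkSet]:
    """Build the phantom volume, its label mask, and centroid landmarks.

    Mask labels: 0 background, 1..n vertebral bodies (caudal to cranial
    along axis 0), n+1 disc, n+2 vessel. Landmarks are the physical
    centroids of each vertebral body. Deterministic for a fixed config.
    """
    centers0, body_rz, disc_rz, plane_centers, plane_radii, vessel_center = \
        _geometry(config)
    n = config.n_vertebrae
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64)
                          for s in config.shape], indexing="ij")
    labels = np.zeros(config.shape, dtype=np.int32)

    # in-plane super-ellipse profile shared by bodies and discs (exponent 4
    # gives the blocky vertebral-body cross-section)
    plane_term = np.zeros(config.shape)
    for ax, (c, r) in enumerate(zip(plane_centers, plane_radii), start=1):
        plane_term = plane_term + np.abs((grids[ax] - c) / r) ** 4

    for k in range(n):
        body = np.abs((grids[0] - centers0[k]) / body_rz) ** 4 \
            + plane_term <= 1.0
        labels[body] = k + 1

    disc_label = n + 1
    for k in range(1, n):
        boundary = k * (config.shape[0] / n)
        band = (np.abs(grids[0] - boundary) <= disc_rz) \
            & (plane_term <= 0.8 ** 4)
        labels[band & (labels == 0)] = disc_label

    vessel_label = n + 2
    vessel_term = np.zeros(config.shape)
    for ax, c in enumerate(vessel_center, start=1):
        vessel_term = vessel_term + ((grids[ax] - c)
                                     / config.vessel_radius) ** 2
    vessel = vessel_term <= 1.0
    labels[vessel & (labels == 0)] = vessel_label

    levels = config.intensity_levels
    lut = np.full(n + 3, levels["background"])
    lut[1:n + 1] = levels["vertebra"]
    lut[disc_label] = levels["disc"]
    lut[vessel_label] = levels["vessel"]
    data = lut[labels]

    volume = ImageVolume(data, config.spacing)
    mask = LabelMask(labels, config.spacing)
    if config.noise_sd > 0:
        volume = add_noise(volume, config.noise_sd, config.seed)

    centroids = []
    for k in range(1, n + 1):
        idx = np.argwhere(labels == k).mean(axis=0)
        centroids.append(volume.voxel_to_physical(idx))
    landmarks = LandmarkSet(np.asarray(centroids))
    return volume, mask, landmarks


def random_deformation(config: PhantomConfig, max_displacement: float,
                       grid_spacing=None) -> BSplineTransform:
    """Seeded random FFD covering the phantom domain.

    Control-point displacement components are drawn i.i.d. uniform in
    ``[-max_displacement, +max_displacement]`` (mm). ``grid_spacing``
    defaults to a quarter of the physical extent per axis, giving a
    smooth, low-frequency ground-truth field.
    """
    if max_displacement < 0:
        raise ConfigError("max_displacement must be >= 0")
    dummy = ImageVolume(np.zeros(config.shape), config.spacing)
    if grid_spacing is None:
        extent = (np.asarray(config.shape) - 1) * np.asarray(config.spacing)
        grid_spacing = np.maximum(extent / 4.0, np.asarray(config.spacing))
    transform = BSplineTransform.identity_for_domain(dummy, grid_spacing)
    rng = np.random.default_rng([config.seed, _STREAM_DEFORM])
    transform.phi = rng.uniform(-max_displacement, max_displacement,
                                size=transform.phi.shape)
    return transform


def add_noise(volume: ImageVolume, sd: float, seed: int) -> ImageVolume:
    """Additive i.i.d. Gaussian noise; the input volume is untouched."""
    if sd < 0:
        raise ValueError("noise standard deviation must be >= 0")
    if sd == 0:
        return volume.copy_with(volume.data.copy())
    rng = np.random.default_rng([seed, _STREAM_NOISE])
    return volume.copy_with(volume.data + rng.normal(0.0, sd, volume.shape))


def segmentation_dataset(n_images: int, config: PhantomConfig | None = None,
                         max_displacement: float = 3.0,
                         n_classes: int = 2,
                         ) -> list[tuple[ImageVolume, LabelMask]]:
    """Phantom image/mask pairs for segmenter training and evaluation.

    Each pair is the base phantom warped by an independently seeded
    random deformation (geometric variety) with noise at the configured
    level. ``n_classes=2`` collapses labels to background/vertebra;
    ``n_classes=3`` keeps the vessel as a third class.
    """
    if n_classes not in (2, 3):
        raise ConfigError("n_classes must be 2 or 3")
    config = config or PhantomConfig()
    pairs = []
    for i in range(n_images):
        cfg_i = PhantomConfig(shape=config.shape,
                              n_vertebrae=config.n_vertebrae,
                              vessel_radius=config.vessel_radius,
                              intensity_levels=config.intensity_levels,
                              noise_sd=0.0,
                              seed=config.seed,
                              spacing=config.spacing)
        volume, mask, _ = generate_phantom(cfg_i)
        cfg_i.seed = int(np.random.default_rng(
            [config.seed, _STREAM_DATASET, i]).integers(0, 2 ** 31))
        if max_displacement > 0:
            t = random_deformation(cfg_i, max_displacement)
            volume = t.warp_image(volume)
            mask = t.warp_mask(mask)
        if config.noise_sd > 0:
            volume = add_noise(volume, config.noise_sd, cfg_i.seed)
        n = config.n_vertebrae
        lab = mask.labels
        out = np.zeros_like(lab)
        out[(lab >= 1) & (lab <= n)] = 1
        if n_classes == 3:
            out[lab == n + 2] = 2
        pairs.append((volume, LabelMask(out, mask.spacing, mask.origin)))
    return pairs
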