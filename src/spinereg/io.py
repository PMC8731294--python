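"""Core grid types and NIfTI / landmark-table I/O.

Conventions used throughout the package:

* arrays are indexed ``[z][y][x]`` (3D) or ``[y][x]`` (2D);
* ``spacing`` and ``origin`` follow the same axis order as the array,
  in millimetres;
* indexing is 0-based and coordinates are voxel-center based, so the
  physical coordinate of voxel ``i`` along an axis is
  ``origin + i * spacing``;
* landmark tables list one point per row in the same axis order as
  ``spacing`` (``z y x`` for 3D points, ``y x`` for 2D).

NIfTI files are read and written through :mod:`nibabel`. Only
axis-aligned, positively scaled orientation matrices are accepted;
anything else is rejected rather than silently reoriented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import FormatError

__all__ = [
    "ImageVolume",
    "LabelMask",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_landmarks",
    "write_landmarks",
]


def _as_tuple(values, ndim: int, name: str) -> tuple[float, ...]:
    if np.isscalar(values):
        values = (float(values),) * ndim
    values = tuple(float(v) for v in np.asarray(values).ravel())
    if len(values) != ndim:
        raise ValueError(f"{name} must have one entry per array axis "
                         f"({ndim}), got {len(values)}")
    return values


@dataclass
class ImageVolume:
    """A scalar intensity grid with physical voxel spacing and origin.

    Parameters
    ----------
    data : ndarray
        2D ``[y][x]`` or 3D ``[z][y][x]`` array of intensities
        (arbitrary units, stored as float64).
    spacing : sequence of float
        Physical voxel size per axis (mm), same axis order as ``data``.
    origin : sequence of float
        Physical coordinate of voxel index 0 per axis (mm).
    """

    data: np.ndarray
    spacing: tuple[float, ...] = None  # type: ignore[assignment]
    origin: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise ValueError("data must have 2 or 3 axes, got "
                             f"{self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("every axis length must be >= 1")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        if self.origin is None:
            self.origin = (0.0,) * self.data.ndim
        self.spacing = _as_tuple(self.spacing, self.data.ndim, "spacing")
        self.origin = _as_tuple(self.origin, self.data.ndim, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got "
                             f"{self.spacing}")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxel_to_physical(self, index) -> np.ndarray:
        """Physical coordinates (mm) of voxel indices (voxel centers)."""
        index = np.asarray(index, dtype=np.float64)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def physical_to_voxel(self, point) -> np.ndarray:
        """Continuous voxel indices of physical coordinates (mm)."""
        point = np.asarray(point, dtype=np.float64)
        return (point - np.asarray(self.origin)) / np.asarray(self.spacing)

    def grid_points(self, stride: int = 1) -> np.ndarray:
        """Physical coordinates of every ``stride``-th voxel center.

        Returns an ``(n_points, ndim)`` array in the package axis order.
        """
        axes = [np.arange(0, n, stride) for n in self.shape]
        mesh = np.meshgrid(*axes, indexing="ij")
        idx = np.stack([m.ravel() for m in mesh], axis=1).astype(np.float64)
        return self.voxel_to_physical(idx)

    def copy_with(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(np.asarray(data, dtype=np.float64),
                           self.spacing, self.origin)


@dataclass
class LabelMask:
    """An integer-labelled grid aligned with a companion :class:`ImageVolume`.

    Background is label 0; structures use positive integer labels.
    """

    labels: np.ndarray
    spacing: tuple[float, ...] = None  # type: ignore[assignment]
    origin: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.array_equal(rounded, labels):
                raise ValueError("labels must be integers")
            labels = rounded
        labels = labels.astype(np.int32)
        if labels.min(initial=0) < 0:
            raise ValueError("labels must be nonnegative")
        self.labels = labels
        if self.ndim not in (2, 3):
            raise ValueError("labels must have 2 or 3 axes")
        if self.spacing is None:
            self.spacing = (1.0,) * self.ndim
        if self.origin is None:
            self.origin = (0.0,) * self.ndim
        self.spacing = _as_tuple(self.spacing, self.ndim, "spacing")
        self.origin = _as_tuple(self.origin, self.ndim, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def ndim(self) -> int:
        return self.labels.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def region(self, label: int) -> np.ndarray:
        """Boolean array selecting voxels carrying ``label``."""
        return self.labels == int(label)

    def matches(self, volume: ImageVolume) -> bool:
        return (self.shape == volume.shape
                and self.spacing == volume.spacing
                and self.origin == volume.origin)


@dataclass
class LandmarkSet:
    """Physical landmark coordinates, optionally paired with correspondences.

    ``points`` is an ``(l, ndim)`` array of coordinates in mm (package
    axis order); ``paired_points`` holds the corresponding positions
    ``x'_i`` when known.
    """

    points: np.ndarray
    paired_points: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")
        if self.paired_points is not None:
            self.paired_points = np.atleast_2d(
                np.asarray(self.paired_points, dtype=np.float64))
            if not np.all(np.isfinite(self.paired_points)):
                raise ValueError("paired coordinates must be finite")
            if self.paired_points.shape != self.points.shape:
                raise ValueError(
                    "paired_points must match points in shape, got "
                    f"{self.paired_points.shape} vs {self.points.shape}")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def is_paired(self) -> bool:
        return self.paired_points is not None


# ---------------------------------------------------------------------------
# NIfTI I/O


def _check_affine(affine: np.ndarray, path) -> tuple[np.ndarray, np.ndarray]:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-6 * max(1.0, np.max(np.abs(rot))):
        raise FormatError(
            f"{path}: orientation matrix is not axis-aligned; this reader "
            "refuses to guess a reorientation")
    scales = np.diag(rot)
    if np.any(scales <= 0):
        raise FormatError(
            f"{path}: orientation includes axis flips or zero scales; only "
            "positive axis-aligned scalings are supported")
    return scales, affine[:3, 3]


def _load_nifti(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.get_fdata())  # slope/intercept applied once
        affine = img.affine
    except (nib.filebasedimages.ImageFileError, OSError, ValueError) as exc:
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    if data.ndim == 3 and data.shape[2] == 1:
        pass  # keep genuine single-slice volumes 3D
    if data.ndim not in (2, 3):
        raise FormatError(f"{path}: expected a 2D or 3D image, got "
                          f"{data.ndim} axes")
    scales, origin = _check_affine(affine, path)
    ndim = data.ndim
    # NIfTI axis order is x fastest; internal order is [z][y][x].
    data = data.T
    spacing = tuple(float(s) for s in scales[:ndim][::-1])
    orig = tuple(float(o) for o in origin[:ndim][::-1])
    return data, spacing, orig


def read_volume(path) -> ImageVolume:
    """Read a scalar image volume from a NIfTI (.nii / .nii.gz) file."""
    data, spacing, origin = _load_nifti(path)
    return ImageVolume(data, spacing, origin)


def read_mask(path) -> LabelMask:
    """Read an integer label mask from a NIfTI file."""
    data, spacing, origin = _load_nifti(path)
    return LabelMask(np.rint(data).astype(np.int32), spacing, origin)


def _write_nifti(data: np.ndarray, spacing, origin, path) -> None:
    ndim = data.ndim
    affine = np.eye(4)
    # back to x-fastest order for the header
    sp = list(spacing[::-1]) + [1.0] * (3 - ndim)
    org = list(origin[::-1]) + [0.0] * (3 - ndim)
    affine[:3, :3] = np.diag(sp)
    affine[:3, 3] = org
    img = nib.Nifti1Image(np.asarray(data).T, affine)
    img.header.set_zooms(tuple(sp[:ndim]))
    nib.save(img, str(path))


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI; round-trips bit-exactly through float64."""
    _write_nifti(volume.data, volume.spacing, volume.origin, path)


def write_mask(mask: LabelMask, path) -> None:
    """Write a label mask as an integer NIfTI."""
    _write_nifti(mask.labels.astype(np.int32), mask.spacing, mask.origin, path)


# ---------------------------------------------------------------------------
# Landmark tables


def read_landmarks(path) -> LandmarkSet:
    """Read a plain-text landmark table.

    One point per row, whitespace- or comma-delimited, ``#`` comments
    allowed. 2 or 3 columns give unpaired points; 4 (2D) or 6 (3D)
    columns give paired points ``x_i x'_i``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        try:
            row = [float(p) for p in parts]
        except ValueError as exc:
            raise FormatError(
                f"{path}:{lineno}: non-numeric field in landmark row") from exc
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no landmark rows found")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (column counts {sorted(widths)})")
    (width,) = widths
    table = np.asarray(rows, dtype=np.float64)
    if width in (2, 3):
        return LandmarkSet(table)
    if width in (4, 6):
        half = width // 2
        return LandmarkSet(table[:, :half], table[:, half:])
    raise FormatError(
        f"{path}: landmark rows must have 2, 3, 4 or 6 columns, got {width}")


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    """Write a landmark table readable by :func:`read_landmarks`."""
    if landmarks.is_paired:
        table = np.hstack([landmarks.points, landmarks.paired_points])
    else:
        table = landmarks.points
    header = ("landmark coordinates (mm), package axis order; paired columns "
              "are x then x'") if landmarks.is_paired else \
        "landmark coordinates (mm), package axis order"
    np.savetxt(str(path), table, fmt="%.17g", header=header)
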