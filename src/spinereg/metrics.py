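"""Registration and segmentation accuracy metrics.

Overlap between a reference region Q and a test region W:

    Dice = 2|Q ∩ W| / (|Q| + |W|),    J = |Q ∩ W| / |Q ∪ W|

which satisfy D = 2J / (1 + J) exactly. When both regions are empty the
metrics are defined as 1 (perfect agreement of empty sets); when exactly
one is empty, 0.

Landmark accuracy is the mean target registration error

    mTRE = (1/l) * sum_i || G(x_i) - x'_i ||

over paired landmarks (x_i, x'_i) in mm.

The noise statistic is the sample standard deviation of intensities
inside a region of interest, normalized by the volume's dynamic range
(dimensionless).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ImageVolume, LabelMask, LandmarkSet

__all__ = ["OverlapReport", "overlap", "dice", "jaccard", "mean_tre",
           "noise_level"]


@dataclass
class OverlapReport:
    """Voxel-count overlap between a reference and a test region."""

    dice: float
    jaccard: float
    n_ref: int
    n_test: int
    n_intersect: int


def _region(mask, label) -> np.ndarray:
    if isinstance(mask, LabelMask):
        arr = mask.labels
    else:
        arr = np.asarray(mask)
    if arr.dtype == bool and label is None:
        return arr
    if label is None:
        return arr > 0
    return arr == int(label)


def overlap(Q, W, label: int | None = None) -> OverlapReport:
    """Dice/Jaccard overlap between regions of two same-shaped masks.

    ``label`` selects the region by label value; ``None`` selects all
    foreground (nonzero) voxels.
    """
    q = _region(Q, label)
    w = _region(W, label)
    if q.shape != w.shape:
        raise ValueError(f"mask shapes differ: {q.shape} vs {w.shape}")
    n_q = int(q.sum())
    n_w = int(w.sum())
    n_qw = int((q & w).sum())
    n_union = n_q + n_w - n_qw
    if n_q == 0 and n_w == 0:
        d = j = 1.0
    elif n_q == 0 or n_w == 0:
        d = j = 0.0
    else:
        d = 2.0 * n_qw / (n_q + n_w)
        j = n_qw / n_union
    return OverlapReport(dice=d, jaccard=j, n_ref=n_q, n_test=n_w,
                         n_intersect=n_qw)


def dice(Q, W, label: int | None = None) -> float:
    """Dice coefficient 2|Q∩W| / (|Q|+|W|) of a labelled region."""
    return overlap(Q, W, label).dice


def jaccard(Q, W, label: int | None = None) -> float:
    """Jaccard index |Q∩W| / |Q∪W| of a labelled region."""
    return overlap(Q, W, label).jaccard


def mean_tre(transform, landmarks: LandmarkSet) -> float:
    """Mean target registration error (mm) over paired landmarks.

    ``transform`` maps each x_i; the error is the Euclidean distance to
    its paired x'_i. ``transform=None`` evaluates the identity (the
    pre-registration error).
    """
    if not landmarks.is_paired:
        raise ValueError("mean_tre requires paired landmarks")
    if transform is None:
        mapped = landmarks.points
    else:
        mapped = transform.transform_points(landmarks.points)
    d = np.linalg.norm(mapped - landmarks.paired_points, axis=1)
    return float(d.mean())


def noise_level(volume: ImageVolume, roi, label: int | None = None) -> float:
    """Normalized noise inside a region of interest.

    Sample standard deviation (ddof=1) of the intensities in the ROI,
    divided by the volume's dynamic range; 0 for a constant volume.
    Comparable across images on a ~0.01-0.1 scale.
    """
    region = _region(roi, label)
    if region.shape != volume.shape:
        raise ValueError("roi shape must match the volume")
    values = volume.data[region]
    if values.size == 0:
        raise ValueError("empty region of interest")
    rng = float(volume.data.max() - volume.data.min())
    if rng == 0 or values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / rng)
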