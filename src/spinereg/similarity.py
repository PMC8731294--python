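"""Mutual information between two images from intensity histograms.

MI is computed twice on every call — once as the entropy combination

    MI(A, B) = K(A) + K(B) - K(A, B)

and once as the double sum

    MI(A, B) = sum_{a,b} p(a,b) * log( p(a,b) / (p(a) p(b)) )

— and the two are required to agree to 1e-9 before the entropy form is
returned. Histograms use hard (nearest-bin) assignment over uniform bins
spanning each image's [min, max]; the maximum intensity falls in the top
bin. Entropies default to bits (log base 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ImageVolume

__all__ = ["JointHistogram", "joint_histogram", "entropy",
           "mutual_information", "mutual_information_from_histogram"]

_FORM_TOL = 1e-9


def _image_data(image) -> np.ndarray:
    if isinstance(image, ImageVolume):
        return image.data
    return np.asarray(image, dtype=np.float64)


@dataclass
class JointHistogram:
    """Joint intensity histogram of two images with its marginals."""

    counts: np.ndarray          # (bins, bins) nonnegative
    p_ab: np.ndarray            # normalized joint probabilities
    p_a: np.ndarray             # marginal of the first image
    p_b: np.ndarray             # marginal of the second image
    bin_edges_a: np.ndarray
    bin_edges_b: np.ndarray
    n_samples: int

    def to_tsv(self, path) -> None:
        """Dump occupied cells as (bin_a, bin_b, count) rows for debugging."""
        ia, ib = np.nonzero(self.counts)
        rows = np.stack([ia, ib, self.counts[ia, ib]], axis=1)
        np.savetxt(str(path), rows, fmt="%d\t%d\t%g",
                   header="bin_a\tbin_b\tcount")


def _edges(values: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:  # constant image: a single occupied bin, not an error
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, bins + 1)


def joint_histogram(A, B, bins: int = 32, mask=None) -> JointHistogram:
    """Joint histogram of two same-shaped images.

    ``mask``, when given, restricts counting to the selected voxels
    (the overlap-region convention used during registration).
    """
    a = _image_data(A)
    b = _image_data(B)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    a = a.ravel()
    b = b.ravel()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool).ravel()
        if mask.shape != a.shape:
            raise ValueError("mask shape must match the images")
        a, b = a[mask], b[mask]
    if a.size == 0:
        raise ValueError("no voxels left to histogram (empty overlap)")
    edges_a = _edges(a, bins)
    edges_b = _edges(b, bins)
    counts, _, _ = np.histogram2d(a, b, bins=[edges_a, edges_b])
    n = int(counts.sum())
    p_ab = counts / n
    return JointHistogram(counts=counts, p_ab=p_ab,
                          p_a=p_ab.sum(axis=1), p_b=p_ab.sum(axis=0),
                          bin_edges_a=edges_a, bin_edges_b=edges_b,
                          n_samples=n)


def entropy(p, base: float = 2.0) -> float:
    """Shannon entropy -sum p log p with 0 log 0 := 0.

    ``p`` may be a probability vector or table; it must be nonnegative
    and sum to 1 within 1e-6.
    """
    p = np.asarray(p, dtype=np.float64).ravel()
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"probabilities must sum to 1, got {total}")
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(base))).sum())


def mutual_information_from_histogram(hist: JointHistogram,
                                      base: float = 2.0) -> float:
    """MI from a joint histogram, cross-checking both computation forms."""
    k_a = entropy(hist.p_a, base)
    k_b = entropy(hist.p_b, base)
    k_ab = entropy(hist.p_ab, base)
    mi_entropy = k_a + k_b - k_ab
    # double-sum form over occupied cells
    nz = hist.p_ab > 0
    pa = np.broadcast_to(hist.p_a[:, None], hist.p_ab.shape)[nz]
    pb = np.broadcast_to(hist.p_b[None, :], hist.p_ab.shape)[nz]
    pab = hist.p_ab[nz]
    mi_sum = float((pab * (np.log(pab / (pa * pb)) / np.log(base))).sum())
    if abs(mi_entropy - mi_sum) > _FORM_TOL:
        raise AssertionError(
            "internal inconsistency: entropy-difference and double-sum MI "
            f"forms disagree by {abs(mi_entropy - mi_sum):.3e}")
    return mi_entropy


def mutual_information(A, B, bins: int = 32, mask=None,
                       base: float = 2.0) -> float:
    """Mutual information between two same-shaped images (bits by default)."""
    return mutual_information_from_histogram(
        joint_histogram(A, B, bins=bins, mask=mask), base=base)
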