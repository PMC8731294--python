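"""Composite registration objective: similarity plus bending energy.

The objective minimized during registration is

    C(mu) = alpha1 * F(mu) + alpha2 * V(mu)

where ``F = -MI(A, warp(B))`` (negated so that minimizing C maximizes
mutual information) and ``V`` is the distortion (bending) energy of the
displacement field: the mean over M sampled voxel centers of

    Phi = (Gxx)^2 + (Gyy)^2 + (Gzz)^2 + 2(Gxy)^2 + 2(Gxz)^2 + 2(Gyz)^2

summed over the displacement components. V is zero exactly when the
field has no second-order variation (identity or any affine field), so
the penalty discourages locally crumpled warps without biasing against
global translation.

An equivalent single-weight form C = F + lambda * V is exposed through
``CostConfig.from_lambda`` (alpha1 = 1, alpha2 = lambda).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bspline import BSplineTransform
from .io import ImageVolume
from .similarity import mutual_information

__all__ = ["CostConfig", "CostValue", "bending_energy", "total_cost"]


@dataclass
class CostConfig:
    """Weights and sampling settings for the composite cost."""

    alpha1: float = 1.0
    alpha2: float = 0.01
    bins: int = 32
    sample_stride: int = 1

    def __post_init__(self) -> None:
        if self.alpha1 <= 0:
            raise ValueError("alpha1 must be > 0")
        if self.alpha2 < 0:
            raise ValueError("alpha2 must be >= 0")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")

    @property
    def lambda_(self) -> float:
        """Penalty weight in the single-weight form C = F + lambda V."""
        return self.alpha2 / self.alpha1

    @classmethod
    def from_lambda(cls, lambda_: float, **kwargs) -> "CostConfig":
        return cls(alpha1=1.0, alpha2=float(lambda_), **kwargs)


@dataclass
class CostValue:
    """Decomposed cost: total = alpha1 * similarity + alpha2 * bending."""

    total: float
    mi: float
    similarity: float  # F = -MI
    bending: float
    n_overlap: int


def bending_energy(transform: BSplineTransform, domain: ImageVolume,
                   stride: int = 1) -> float:
    """Mean squared-curvature of the displacement field over ``domain``.

    Samples every ``stride``-th voxel center of ``domain`` and averages
    the analytic bending density there.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    points = domain.grid_points(stride)
    return float(transform.bending_density(points).mean())


def total_cost(transform: BSplineTransform, A: ImageVolume, B: ImageVolume,
               config: CostConfig | None = None) -> CostValue:
    """Evaluate C(mu) for floating image B warped onto reference A.

    B is backward-warped by the transform, MI is computed between A and
    the warped B over the overlap region (samples that fell outside B
    are excluded), and the bending energy is averaged over the sampled
    voxel centers of A's grid.
    """
    config = config or CostConfig()
    if A.shape != B.shape:
        raise ValueError(f"image shapes differ: {A.shape} vs {B.shape}")
    warped, valid = transform.warp_image(B, interpolation="linear",
                                         return_valid=True)
    stride = config.sample_stride
    if stride > 1:
        slicer = tuple(slice(None, None, stride) for _ in range(A.ndim))
        mi = mutual_information(A.data[slicer], warped.data[slicer],
                                bins=config.bins, mask=valid[slicer])
        n_overlap = int(valid[slicer].sum())
    else:
        mi = mutual_information(A, warped, bins=config.bins, mask=valid)
        n_overlap = int(valid.sum())
    v = bending_energy(transform, A, stride=stride)
    total = config.alpha1 * (-mi) + config.alpha2 * v
    return CostValue(total=float(total), mi=float(mi), similarity=float(-mi),
                     bending=float(v), n_overlap=n_overlap)
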