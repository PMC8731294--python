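"""Cubic B-spline free-form deformation (FFD).

The transform is parameterized by a regular lattice of control-point
displacement vectors ``phi``. A physical point ``x`` maps to local
lattice coordinates ``u = (x - grid_origin) / grid_spacing``; with
``d = floor(u)`` and fractional offset ``n = u - d`` the displacement is
the tensor-product sum over the 4 surrounding control points per axis::

    disp(x) = sum_{l,a,b in 0..3} R_l(n_z) R_a(n_y) R_b(n_x)
              phi[d_z+l, d_y+a, d_x+b]

with the uniform cubic B-spline basis

    R0(n) = (1-n)^3 / 6
    R1(n) = (3n^3 - 6n^2 + 4) / 6
    R2(n) = (-3n^3 + 3n^2 + 3n + 1) / 6
    R3(n) = n^3 / 6

The basis is a partition of unity (sum_l R_l(n) = 1), so an all-equal
lattice reproduces an exact global translation, and the field is C^2,
with analytic first and second derivatives used by the bending-energy
penalty.

The lattice must extend at least one control point beyond the image
domain on every side so the indices ``d+l`` always exist; the
:meth:`BSplineTransform.for_domain` factory takes care of the padding.
2D images are the degenerate case with one lattice axis per array axis
and no z terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .exceptions import DomainError
from .io import ImageVolume, LabelMask

__all__ = ["basis", "basis_d1", "basis_d2", "BSplineTransform",
           "LocalCoordinate"]

_EPS_DOMAIN = 1e-9


def _poly(l: int, n, order: int):
    n = np.asarray(n, dtype=np.float64)
    if order == 0:
        if l == 0:
            return (1.0 - n) ** 3 / 6.0
        if l == 1:
            return (3.0 * n ** 3 - 6.0 * n ** 2 + 4.0) / 6.0
        if l == 2:
            return (-3.0 * n ** 3 + 3.0 * n ** 2 + 3.0 * n + 1.0) / 6.0
        if l == 3:
            return n ** 3 / 6.0
    elif order == 1:
        if l == 0:
            return -0.5 * (1.0 - n) ** 2
        if l == 1:
            return 1.5 * n ** 2 - 2.0 * n
        if l == 2:
            return -1.5 * n ** 2 + n + 0.5
        if l == 3:
            return 0.5 * n ** 2
    elif order == 2:
        if l == 0:
            return 1.0 - n
        if l == 1:
            return 3.0 * n - 2.0
        if l == 2:
            return 1.0 - 3.0 * n
        if l == 3:
            return np.asarray(n, dtype=np.float64).copy()
    raise ValueError(f"basis index l must be in 0..3, got {l}")


def basis(l: int, n):
    """Cubic B-spline basis weight R_l(n) for l in 0..3, n in [0, 1)."""
    if not 0 <= int(l) <= 3:
        raise ValueError(f"basis index l must be in 0..3, got {l}")
    return _poly(int(l), n, 0)


def basis_d1(l: int, n):
    """First derivative dR_l/dn."""
    if not 0 <= int(l) <= 3:
        raise ValueError(f"basis index l must be in 0..3, got {l}")
    return _poly(int(l), n, 1)


def basis_d2(l: int, n):
    """Second derivative d^2 R_l / dn^2."""
    if not 0 <= int(l) <= 3:
        raise ValueError(f"basis index l must be in 0..3, got {l}")
    return _poly(int(l), n, 2)


@dataclass
class LocalCoordinate:
    """Lattice cell index and fractional offset of a physical point."""

    cell: np.ndarray  # integer cell index per axis
    frac: np.ndarray  # fractional offset per axis, each in [0, 1)


@dataclass
class BSplineTransform:
    """Free-form deformation on a regular control-point lattice.

    Parameters
    ----------
    phi : ndarray, shape grid_shape + (ndim,)
        Displacement vector (mm) stored at every control point, in the
        package axis order (``[z][y][x]`` / ``[y][x]``).
    grid_spacing : sequence of float
        Physical distance between adjacent control points per axis (mm).
    grid_origin : sequence of float
        Physical coordinate of control point index 0 per axis (mm).
    """

    phi: np.ndarray
    grid_spacing: tuple[float, ...]
    grid_origin: tuple[float, ...]

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=np.float64)
        ndim = self.phi.ndim - 1
        if ndim not in (2, 3) or self.phi.shape[-1] != ndim:
            raise ValueError(
                "phi must have shape grid_shape + (ndim,) with ndim 2 or 3, "
                f"got {self.phi.shape}")
        if min(self.phi.shape[:-1]) < 4:
            raise ValueError("the lattice needs at least 4 control points "
                             "per axis (cubic support)")
        self.grid_spacing = tuple(
            float(s) for s in np.broadcast_to(
                np.asarray(self.grid_spacing, dtype=np.float64), (ndim,)))
        self.grid_origin = tuple(
            float(o) for o in np.broadcast_to(
                np.asarray(self.grid_origin, dtype=np.float64), (ndim,)))
        if any(s <= 0 for s in self.grid_spacing):
            raise ValueError("grid_spacing must be strictly positive")

    # -- basic geometry ----------------------------------------------------

    @property
    def ndim(self) -> int:
        return self.phi.ndim - 1

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.phi.shape[:-1]

    @property
    def domain_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (lower, upper) bounds within which the FFD is defined.

        A point is in-domain when every axis satisfies
        ``0 <= (x - origin)/spacing < n_ctrl - 3``.
        """
        g = np.asarray(self.grid_origin)
        d = np.asarray(self.grid_spacing)
        n = np.asarray(self.grid_shape, dtype=np.float64)
        return g, g + (n - 3.0) * d

    @classmethod
    def identity_for_domain(cls, volume: ImageVolume | LabelMask,
                            grid_spacing) -> "BSplineTransform":
        """Zero-displacement lattice covering ``volume`` plus a padding ring."""
        ndim = volume.ndim
        spacing = np.broadcast_to(
            np.asarray(grid_spacing, dtype=np.float64), (ndim,)).copy()
        lo = np.asarray(volume.origin, dtype=np.float64)
        hi = lo + (np.asarray(volume.shape) - 1) * np.asarray(volume.spacing)
        origin = lo - spacing
        n_ctrl = np.ceil((hi - origin) / spacing).astype(int) + 4
        phi = np.zeros(tuple(n_ctrl) + (ndim,))
        return cls(phi, tuple(spacing), tuple(origin))

    # shorter alias
    for_domain = identity_for_domain

    # -- evaluation ---------------------------------------------------------

    def _local(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        if pts.shape[1] != self.ndim:
            raise ValueError(f"points must be (n, {self.ndim})")
        u = (pts - np.asarray(self.grid_origin)) / np.asarray(self.grid_spacing)
        cell = np.floor(u).astype(np.int64)
        # points exactly on the upper domain edge belong to the last cell
        upper = np.asarray(self.grid_shape) - 4
        at_edge = (cell == upper + 1) & (
            np.abs(u - cell) < _EPS_DOMAIN)
        cell = np.where(at_edge, cell - 1, cell)
        frac = u - cell
        if np.any(cell < 0) or np.any(cell > upper):
            bad = np.where((cell < 0) | (cell > upper))[0][0]
            raise DomainError(
                f"point {pts[bad]} lies outside the transform domain "
                f"{self.domain_bounds}")
        return cell, frac

    def to_local(self, point) -> LocalCoordinate:
        """Map a physical point to its lattice cell and fractional offset."""
        cell, frac = self._local(np.atleast_2d(point))
        return LocalCoordinate(cell[0], frac[0])

    def _weights(self, frac: np.ndarray, orders) -> list[np.ndarray]:
        """Per-axis (n_points, 4) basis weight tables.

        ``orders[ax]`` selects the derivative order of the basis along
        that axis; derivative orders carry the 1/spacing chain factors.
        """
        out = []
        for ax in range(self.ndim):
            w = np.stack([_poly(l, frac[:, ax], orders[ax])
                          for l in range(4)], axis=1)
            if orders[ax] > 0:
                w = w / (self.grid_spacing[ax] ** orders[ax])
            out.append(w)
        return out

    def _evaluate(self, points, orders) -> np.ndarray:
        """Tensor-product sum over the 4^ndim supporting control points."""
        cell, frac = self._local(points)
        weights = self._weights(frac, orders)
        n_pts = cell.shape[0]
        result = np.zeros((n_pts, self.ndim))
        for offs in product(range(4), repeat=self.ndim):
            w = weights[0][:, offs[0]]
            for ax in range(1, self.ndim):
                w = w * weights[ax][:, offs[ax]]
            idx = tuple(cell[:, ax] + offs[ax] for ax in range(self.ndim))
            result += w[:, None] * self.phi[idx]
        return result

    def displacement(self, points) -> np.ndarray:
        """Displacement vectors (mm) at physical points, shape (n, ndim)."""
        return self._evaluate(points, (0,) * self.ndim)

    def transform_points(self, points) -> np.ndarray:
        """Apply the FFD to an ``(n, ndim)`` array of physical points."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts + self.displacement(pts)

    def transform_point(self, point) -> np.ndarray:
        """Apply the FFD to a single physical point."""
        return self.transform_points(np.atleast_2d(point))[0]

    # -- derivatives ---------------------------------------------------------

    def hessian(self, points) -> np.ndarray:
        """Analytic Hessians of the displacement field.

        Returns ``(n_points, ndim, ndim, ndim)``: for each point, each
        displacement component, the symmetric matrix of second partials
        with respect to the physical axes (package axis order).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        n_pts = pts.shape[0]
        D = self.ndim
        H = np.zeros((n_pts, D, D, D))
        for i in range(D):
            for j in range(i, D):
                orders = [0] * D
                orders[i] += 1
                orders[j] += 1
                val = self._evaluate(pts, tuple(orders))
                H[:, :, i, j] = val
                H[:, :, j, i] = val
        return H

    def second_derivatives(self, points) -> np.ndarray:
        """Six-component second derivatives per displacement component.

        Returns ``(n_points, ndim, 6)`` ordered
        ``(xx, yy, zz, xy, xz, yz)`` where x is the fastest (last) array
        axis. For 2D transforms all z components are zero.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        H = self.hessian(pts)
        D = self.ndim
        # physical axis labels: last array axis is x, then y, then z
        ax_x, ax_y = D - 1, D - 2
        ax_z = D - 3 if D == 3 else None
        n_pts = pts.shape[0]
        out = np.zeros((n_pts, D, 6))
        out[:, :, 0] = H[:, :, ax_x, ax_x]
        out[:, :, 1] = H[:, :, ax_y, ax_y]
        out[:, :, 3] = H[:, :, ax_x, ax_y]
        if ax_z is not None:
            out[:, :, 2] = H[:, :, ax_z, ax_z]
            out[:, :, 4] = H[:, :, ax_x, ax_z]
            out[:, :, 5] = H[:, :, ax_y, ax_z]
        return out

    def bending_density(self, points) -> np.ndarray:
        """Squared-curvature density at each point.

        ``sum_components (Gxx^2 + Gyy^2 + Gzz^2 + 2Gxy^2 + 2Gxz^2 + 2Gyz^2)``
        — i.e. the squared Frobenius norm of the displacement Hessians.
        """
        H = self.hessian(points)
        return np.einsum("ncij,ncij->n", H, H)

    # -- warping --------------------------------------------------------------

    def warp_image(self, volume: ImageVolume, interpolation: str = "linear",
                   return_valid: bool = False):
        """Backward-warp ``volume``: output(p) = input(T(p)).

        Samples falling outside the input grid are filled with 0; the
        optional validity mask marks in-range samples (used to restrict
        similarity measures to the overlap region).
        """
        if interpolation not in ("nearest", "linear"):
            raise ValueError(
                f"interpolation must be 'nearest' or 'linear', got "
                f"{interpolation!r}")
        order = 0 if interpolation == "nearest" else 1
        pts = volume.grid_points()
        mapped = self.transform_points(pts)
        coords = (mapped - np.asarray(volume.origin)) / np.asarray(
            volume.spacing)
        valid = np.all((coords >= 0)
                       & (coords <= np.asarray(volume.shape) - 1), axis=1)
        sampled = ndimage.map_coordinates(
            volume.data, coords.T, order=order, mode="constant", cval=0.0)
        out = volume.copy_with(sampled.reshape(volume.shape))
        if return_valid:
            return out, valid.reshape(volume.shape)
        return out

    def warp_mask(self, mask: LabelMask) -> LabelMask:
        """Backward-warp a label mask with nearest-neighbour sampling."""
        vol = ImageVolume(mask.labels.astype(np.float64), mask.spacing,
                          mask.origin)
        warped = self.warp_image(vol, interpolation="nearest")
        return LabelMask(np.rint(warped.data).astype(np.int32),
                         mask.spacing, mask.origin)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "spinereg-bspline-transform",
            "version": 1,
            "grid_shape": list(self.grid_shape),
            "grid_spacing": list(self.grid_spacing),
            "grid_origin": list(self.grid_origin),
            "phi": self.phi.ravel().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineTransform":
        if d.get("format") != "spinereg-bspline-transform":
            raise ValueError("not a serialized B-spline transform")
        shape = tuple(int(n) for n in d["grid_shape"])
        phi = np.asarray(d["phi"], dtype=np.float64).reshape(
            shape + (len(shape),))
        return cls(phi, tuple(d["grid_spacing"]), tuple(d["grid_origin"]))

    def save(self, path) -> None:
        """Serialize to YAML or JSON (by file extension); round-trip exact."""
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d))
        else:
            path.write_text(json.dumps(d))

    @classmethod
    def load(cls, path) -> "BSplineTransform":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
            else json.loads(text)
        return cls.from_dict(d)
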