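"""Deformable registration: minimize the composite MI + bending cost.

Solves ``mu_hat = argmin_mu C(mu; A, B)`` over the control-point
displacements of a cubic B-spline FFD, using a deterministic greedy
coordinate descent: control points are scanned in a fixed order, each
displacement component is tried at +/- the current step, the first
improving move is accepted, and the step is halved whenever a full sweep
yields no improvement. The search is wrapped in a coarse-to-fine loop
over both image resolution (block-mean pyramid, factor 2) and
control-grid spacing; each finer level starts from the coarse solution
resampled onto the finer lattice.

MI has no convenient analytic gradient through a hard-binned histogram,
so the optimizer is derivative-free by design; the per-candidate cost is
kept cheap by precomputing the (voxels x control points) B-spline weight
matrices once per level, after which a candidate evaluation is a dense
matrix product, an interpolation, and a histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .bspline import BSplineTransform, _poly
from .cost import CostConfig, CostValue
from .io import ImageVolume
from .similarity import JointHistogram, mutual_information_from_histogram

__all__ = ["RegistrationConfig", "RegistrationResult", "register",
           "BSplineRegistration"]


@dataclass
class RegistrationConfig:
    """Settings for the multiresolution coordinate-descent optimizer.

    ``grid_spacing_schedule`` lists control-point spacings (mm) from
    coarse to fine, one optimization level per entry; each level also
    halves the image pyramid factor. ``step_init`` is the first trial
    displacement (mm); steps halve down to ``min_step``.
    """

    grid_spacing_schedule: tuple[float, ...] = (16.0, 8.0)
    max_iters: int = 40
    tol: float = 1e-3
    step_init: float = 2.0
    min_step: float = 0.05
    smooth_sigma: float = 1.0
    pyramid: bool = True
    seed: int = 0
    # MI is O(1) bits while the bending density of a few-mm field on a
    # ~16 mm lattice is O(1e-4), so the default penalty weight is O(100)
    cost: CostConfig = field(
        default_factory=lambda: CostConfig(alpha2=200.0))

    def __post_init__(self) -> None:
        sched = tuple(float(s) for s in self.grid_spacing_schedule)
        if not sched:
            raise ValueError("grid_spacing_schedule must be nonempty")
        if any(b > a + 1e-12 for a, b in zip(sched, sched[1:])):
            raise ValueError("grid_spacing_schedule must be non-increasing")
        self.grid_spacing_schedule = sched
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.step_init <= 0 or self.min_step <= 0:
            raise ValueError("steps must be > 0")


@dataclass
class RegistrationResult:
    """Optimized transform plus the optimization history."""

    transform: BSplineTransform
    cost_trace: list[tuple[float, float, float]]  # (mi, bending, total)
    converged: bool
    levels: list[dict]
    initial_cost: float
    final_cost: float


def _downsample(volume: ImageVolume) -> ImageVolume:
    """Factor-2 block-mean downsampling, preserving physical coordinates."""
    data = volume.data
    slicer = tuple(slice(0, (s // 2) * 2) for s in data.shape)
    data = data[slicer]
    for ax in range(data.ndim):
        shape = data.shape[:ax] + (data.shape[ax] // 2, 2) + data.shape[ax + 1:]
        data = data.reshape(shape).mean(axis=ax + 1)
    spacing = tuple(2.0 * s for s in volume.spacing)
    origin = tuple(o + 0.5 * s for o, s in zip(volume.origin, volume.spacing))
    return ImageVolume(data, spacing, origin)


def _weight_matrix(transform: BSplineTransform, points: np.ndarray,
                   orders) -> np.ndarray:
    """Dense (n_points, n_control) B-spline weight matrix.

    ``orders`` selects the basis derivative order per axis (with the
    1/spacing chain factors), so the same construction serves the
    displacement field and every Hessian component.
    """
    cell, frac = transform._local(points)
    D = transform.ndim
    w_ax = []
    for ax in range(D):
        w = np.stack([_poly(l, frac[:, ax], orders[ax]) for l in range(4)],
                     axis=1)
        if orders[ax] > 0:
            w = w / (transform.grid_spacing[ax] ** orders[ax])
        w_ax.append(w)
    n_ctrl = int(np.prod(transform.grid_shape))
    W = np.zeros((points.shape[0], n_ctrl))
    rows = np.arange(points.shape[0])
    for offs in product(range(4), repeat=D):
        w = w_ax[0][:, offs[0]]
        for ax in range(1, D):
            w = w * w_ax[ax][:, offs[ax]]
        idx = np.ravel_multi_index(
            tuple(cell[:, ax] + offs[ax] for ax in range(D)),
            transform.grid_shape)
        np.add.at(W, (rows, idx), w)
    return W


class _LevelProblem:
    """Cached cost evaluation for one resolution level.

    Holds the fixed reference intensities, the floating image, the voxel
    centers, and the precomputed weight matrices; evaluating a candidate
    lattice is then a dense matmul + interpolation + histogram.
    """

    def __init__(self, A: ImageVolume, B: ImageVolume,
                 transform: BSplineTransform, cost: CostConfig):
        self.A = A
        self.B = B
        self.cost = cost
        self.transform = transform
        self.D = transform.ndim
        self.points = A.grid_points()
        stride = cost.sample_stride
        if stride > 1:
            slicer = tuple(slice(None, None, stride) for _ in range(A.ndim))
            self._mi_sel = np.zeros(A.shape, dtype=bool)
            self._mi_sel[slicer] = True
            self._mi_sel = self._mi_sel.ravel()
        else:
            self._mi_sel = slice(None)
        self.a_flat = A.data.ravel()[self._mi_sel]
        self.W = _weight_matrix(transform, self.points, (0,) * self.D)
        bend_points = A.grid_points(stride)
        self.n_bend = bend_points.shape[0]
        self.bend_W = []
        for i in range(self.D):
            for j in range(i, self.D):
                orders = [0] * self.D
                orders[i] += 1
                orders[j] += 1
                mult = 1.0 if i == j else 2.0
                self.bend_W.append(
                    (mult, _weight_matrix(transform, bend_points,
                                          tuple(orders))))
        self._b_origin = np.asarray(B.origin)
        self._b_spacing = np.asarray(B.spacing)
        self._b_upper = np.asarray(B.shape, dtype=np.float64) - 1.0
        self._split_informative()

    def _split_informative(self, grad_frac: float = 0.05) -> None:
        """Partition control points by whether MI can observe them.

        A control point whose support contains no intensity-gradient
        voxel of the reference cannot change the histogram; its optimal
        value is the minimum of the bending energy given its informative
        neighbours — a linear solve, prepared here (Cholesky of the
        uninformative block of the bending normal matrix).
        """
        grad = np.gradient(self.A.data)
        gmag = np.sqrt(sum(g * g for g in grad)).ravel()
        edge_rows = gmag > grad_frac * gmag.max() if gmag.max() > 0 else \
            np.ones_like(gmag, dtype=bool)
        touched = np.abs(self.W[edge_rows]).max(axis=0) > 1e-12
        covered = np.abs(self.W).max(axis=0) > 1e-12
        self.active = np.flatnonzero(touched)
        self.passive = np.flatnonzero(covered & ~touched)
        self._K = None
        if self.passive.size:
            K = np.zeros((self.W.shape[1],) * 2)
            for mult, Wd in self.bend_W:
                K += mult * (Wd.T @ Wd)
            K_uu = K[np.ix_(self.passive, self.passive)]
            K_uu = K_uu + 1e-9 * np.eye(K_uu.shape[0])
            self._K_ua = K[self.passive]  # rows passive, all columns
            self._K_chol = np.linalg.cholesky(K_uu)
            self._K = K

    def smooth_passive(self, phi_flat: np.ndarray) -> None:
        """Set MI-blind control points to the minimal-bending solution."""
        if self._K is None:
            return
        rhs = -(self._K_ua @ phi_flat
                - self._K[np.ix_(self.passive, self.passive)]
                @ phi_flat[self.passive])
        y = np.linalg.solve(self._K_chol, rhs)
        phi_flat[self.passive] = np.linalg.solve(self._K_chol.T, y)

    def evaluate(self, phi_flat: np.ndarray) -> CostValue:
        """Composite cost for a flattened (n_control, ndim) lattice."""
        disp = self.W @ phi_flat
        mapped = self.points + disp
        coords = ((mapped - self._b_origin) / self._b_spacing).T
        valid = np.all((coords >= 0) & (coords <= self._b_upper[:, None]),
                       axis=0)
        sampled = ndimage.map_coordinates(self.B.data, coords, order=1,
                                          mode="constant", cval=0.0)
        sel_valid = valid[self._mi_sel]
        a = self.a_flat[sel_valid]
        b = sampled[self._mi_sel][sel_valid]
        mi = self._mi(a, b)
        v = 0.0
        for mult, Wd in self.bend_W:
            d2 = Wd @ phi_flat
            v += mult * float(np.einsum("ij,ij->", d2, d2))
        v /= self.n_bend
        total = self.cost.alpha1 * (-mi) + self.cost.alpha2 * v
        return CostValue(total=total, mi=mi, similarity=-mi, bending=v,
                         n_overlap=int(a.size))

    def _mi(self, a: np.ndarray, b: np.ndarray) -> float:
        """Hard-binned MI via bincount; same binning convention as
        :func:`spinereg.similarity.joint_histogram`."""
        if a.size == 0:
            raise ValueError("empty overlap region")
        bins = self.cost.bins
        counts = _fast_hist2d(a, b, bins)
        n = int(counts.sum())
        p_ab = counts / n
        hist = JointHistogram(counts=counts, p_ab=p_ab,
                              p_a=p_ab.sum(axis=1), p_b=p_ab.sum(axis=0),
                              bin_edges_a=None, bin_edges_b=None,
                              n_samples=n)
        return mutual_information_from_histogram(hist)


def _fast_hist2d(a: np.ndarray, b: np.ndarray, bins: int) -> np.ndarray:
    idx = np.empty((2, a.size), dtype=np.int64)
    for k, v in enumerate((a, b)):
        lo, hi = float(v.min()), float(v.max())
        if lo == hi:
            idx[k] = 0
        else:
            i = np.floor((v - lo) * (bins / (hi - lo))).astype(np.int64)
            np.clip(i, 0, bins - 1, out=i)
            idx[k] = i
    flat = np.bincount(idx[0] * bins + idx[1], minlength=bins * bins)
    return flat.reshape(bins, bins).astype(np.float64)


def _optimize_level(problem: _LevelProblem, config: RegistrationConfig):
    """Greedy first-improvement coordinate descent on one level."""
    phi = problem.transform.phi.reshape(-1, problem.D).copy()
    current = problem.evaluate(phi)
    trace = [(current.mi, current.bending, current.total)]
    # phase 0: global translation (all control points moved together) —
    # a bending-free mode that per-point moves cannot enter efficiently
    step = config.step_init
    while step >= config.min_step:
        moved = False
        for comp in range(problem.D):
            for delta in (step, -step):
                phi[:, comp] += delta
                trial = problem.evaluate(phi)
                if trial.total < current.total - 1e-12:
                    current = trial
                    moved = True
                    break
                phi[:, comp] -= delta
        if not moved:
            step *= 0.5
    trace.append((current.mi, current.bending, current.total))
    step = config.step_init
    converged = False
    sweeps = 0
    for sweeps in range(1, config.max_iters + 1):
        sweep_start_total = current.total
        for ci in problem.active:
            for comp in range(problem.D):
                # best-of-three move: stay, +step, -step (no directional bias)
                best_delta = 0.0
                best = current
                for delta in (step, -step):
                    phi[ci, comp] += delta
                    trial = problem.evaluate(phi)
                    phi[ci, comp] -= delta
                    if trial.total < best.total - 1e-12:
                        best = trial
                        best_delta = delta
                if best_delta != 0.0:
                    phi[ci, comp] += best_delta
                    current = best
        # park the MI-blind control points at the minimal-bending field
        trial_phi = phi.copy()
        problem.smooth_passive(trial_phi)
        trial = problem.evaluate(trial_phi)
        if trial.total <= current.total:
            phi = trial_phi
            current = trial
        trace.append((current.mi, current.bending, current.total))
        rel = (sweep_start_total - current.total) / max(
            abs(sweep_start_total), 1e-12)
        if rel < config.tol:
            step *= 0.5
            if step < config.min_step:
                converged = True
                break
    problem.transform.phi = phi.reshape(problem.transform.phi.shape)
    return trace, converged, sweeps, current


def register(A: ImageVolume, B: ImageVolume,
             config: RegistrationConfig | None = None) -> RegistrationResult:
    """Register floating image B onto reference image A.

    Returns the best FFD found (mapping reference coordinates into the
    floating image for backward warping), with per-level cost traces.
    Deterministic for fixed inputs and config.
    """
    config = config or RegistrationConfig()
    if A.ndim != B.ndim:
        raise ValueError("images must have the same dimensionality")
    if np.ptp(A.data) == 0 or np.ptp(B.data) == 0:
        raise ValueError("constant image: mutual information is degenerate")

    n_levels = len(config.grid_spacing_schedule)
    # image pyramid aligned with the schedule, coarsest first
    pyr_A, pyr_B = [A], [B]
    if config.pyramid:
        for _ in range(n_levels - 1):
            if min(pyr_A[0].shape) < 16:
                pyr_A.insert(0, pyr_A[0])
                pyr_B.insert(0, pyr_B[0])
            else:
                pyr_A.insert(0, _downsample(pyr_A[0]))
                pyr_B.insert(0, _downsample(pyr_B[0]))
    else:
        pyr_A = [A] * n_levels
        pyr_B = [B] * n_levels

    transform: BSplineTransform | None = None
    levels: list[dict] = []
    finest_trace: list[tuple[float, float, float]] = []
    converged = False
    for lvl, spacing in enumerate(config.grid_spacing_schedule):
        A_l, B_l = pyr_A[lvl], pyr_B[lvl]
        if config.smooth_sigma > 0:
            # piecewise-constant regions carry no MI signal; smoothing
            # spreads edge information inward and smooths the cost
            A_l = A_l.copy_with(
                ndimage.gaussian_filter(A_l.data, config.smooth_sigma))
            B_l = B_l.copy_with(
                ndimage.gaussian_filter(B_l.data, config.smooth_sigma))
        new_t = BSplineTransform.identity_for_domain(A_l, spacing)
        if transform is not None:
            new_t.phi = _resample_lattice(transform, new_t)
        problem = _LevelProblem(A_l, B_l, new_t, config.cost)
        identity_cost = problem.evaluate(
            np.zeros((int(np.prod(new_t.grid_shape)), new_t.ndim))).total
        trace, lvl_converged, sweeps, final = _optimize_level(problem, config)
        transform = problem.transform
        levels.append({
            "level": lvl,
            "grid_spacing": spacing,
            "image_shape": A_l.shape,
            "sweeps": sweeps,
            "trace": trace,
            "identity_cost": identity_cost,
            "converged": lvl_converged,
            "final": (final.mi, final.bending, final.total),
        })
        finest_trace = trace
        converged = lvl_converged
    return RegistrationResult(
        transform=transform,
        cost_trace=finest_trace,
        converged=converged,
        levels=levels,
        initial_cost=finest_trace[0][2],
        final_cost=finest_trace[-1][2],
    )


def _resample_lattice(prev: BSplineTransform,
                      new: BSplineTransform) -> np.ndarray:
    """Initialize a finer lattice from the coarse solution.

    Each new control point takes the coarse field's displacement at its
    physical position (zero outside the coarse domain). Exact for
    translations; a good warm start for smooth fields.
    """
    axes = [np.arange(n, dtype=np.float64) for n in new.grid_shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    pts = np.asarray(new.grid_origin) + pts * np.asarray(new.grid_spacing)
    lo, hi = prev.domain_bounds
    eps = 1e-9
    inside = np.all((pts >= lo + eps) & (pts <= hi - eps), axis=1)
    phi = np.zeros((pts.shape[0], new.ndim))
    if inside.any():
        phi[inside] = prev.displacement(pts[inside])
    return phi.reshape(new.phi.shape)


class BSplineRegistration(BaseEstimator):
    """Estimator-style interface to :func:`register`.

    ``fit(reference, floating)`` optimizes the FFD and stores it as
    ``transform_`` (with the full :class:`RegistrationResult` in
    ``result_``); ``transform(volume)`` then backward-warps a volume by
    the fitted deformation.
    """

    def __init__(self, grid_spacing_schedule=(16.0, 8.0), max_iters=40,
                 tol=1e-3, step_init=2.0, min_step=0.05, smooth_sigma=1.0,
                 pyramid=True, alpha1=1.0, alpha2=200.0, bins=32,
                 sample_stride=1, seed=0):
        self.grid_spacing_schedule = grid_spacing_schedule
        self.max_iters = max_iters
        self.tol = tol
        self.step_init = step_init
        self.min_step = min_step
        self.smooth_sigma = smooth_sigma
        self.pyramid = pyramid
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.bins = bins
        self.sample_stride = sample_stride
        self.seed = seed

    def _config(self) -> RegistrationConfig:
        return RegistrationConfig(
            grid_spacing_schedule=tuple(self.grid_spacing_schedule),
            max_iters=self.max_iters, tol=self.tol, step_init=self.step_init,
            min_step=self.min_step, smooth_sigma=self.smooth_sigma,
            pyramid=self.pyramid, seed=self.seed,
            cost=CostConfig(alpha1=self.alpha1, alpha2=self.alpha2,
                            bins=self.bins, sample_stride=self.sample_stride))

    def fit(self, reference: ImageVolume, floating: ImageVolume
            ) -> "BSplineRegistration":
        result = register(reference, floating, self._config())
        self.result_ = result
        self.transform_ = result.transform
        self.converged_ = result.converged
        self.final_cost_ = result.final_cost
        return self

    def transform(self, volume: ImageVolume, interpolation: str = "linear"
                  ) -> ImageVolume:
        if not hasattr(self, "transform_"):
            raise AttributeError("fit must be called before transform")
        return self.transform_.warp_image(volume, interpolation=interpolation)

    def fit_transform(self, reference: ImageVolume, floating: ImageVolume
                      ) -> ImageVolume:
        return self.fit(reference, floating).transform(floating)
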