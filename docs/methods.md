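# Methods

This note records the models implemented in `spinereg`, the parameter
choices that matter, what the synthetic phantoms do and do not emulate,
and the numerical decisions a maintainer should know about. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate conventions

Arrays are indexed `[z][y][x]` (2D: `[y][x]`); spacing, origin, landmark
coordinates and displacement vectors all follow the same axis order, in
millimetres. Indexing is 0-based and voxel-center based: voxel `i` sits at
`origin + i * spacing`. NIfTI files with any orientation beyond positive
axis-aligned scaling are rejected rather than silently reoriented — the
toolkit refuses to guess.

## Free-form deformation transform

The deformation is a uniform cubic B-spline over a regular control-point
lattice. For a point with lattice coordinate `u = (x - grid_origin)/δ`,
cell `d = floor(u)` and fraction `n = u - d`, the displacement is the
tensor-product sum of `R_l(n)` weights over control points `φ[d+l]`,
`l = 0..3`, per axis. Because the basis is a partition of unity, an
all-equal lattice is an exact global translation, and `φ ≡ 0` is exactly
the identity. The lattice is padded by one control ring beyond the image
domain so the `d+l` indices always exist; the `for_domain` factory
computes the padding. With respect to the common "centered kernel"
description, our `φ[k]` is the node at `grid_origin + (k+1)δ` — a pure
relabeling with no effect on the field (the test suite cross-checks
point transformation against SimpleITK's B-spline transform with the
correspondingly shifted coefficient grid).

First and second derivatives of the field are analytic (polynomial
derivatives of `R_l` with `1/δ` chain factors); the tests verify them
against central finite differences at `10^-3 δ` steps.

Image warping is backward: `output(p) = input(G(p))`, sampled with linear
(default) or nearest-neighbour interpolation; out-of-range samples take
the background value 0, and a validity mask marks them so similarity
measures can exclude non-overlap voxels. Label masks always warp with
nearest-neighbour sampling. 2D images are the degenerate case with no
z-axis terms.

## Mutual information

MI uses a hard-assignment joint histogram: uniform bins spanning each
image's `[min, max]`, with the maximum mapped into the top bin, default
32 bins, entropies in bits. Both the entropy combination
`K(A) + K(B) - K(A,B)` and the direct double sum over
`p(a,b) log p(a,b)/(p(a)p(b))` are evaluated on every call and must agree
to `1e-9`; the entropy form is returned. Bin count, log base and overlap
handling are configuration, chosen as conventional defaults — hard
binning keeps the double-sum definition literal. Parzen/partial-volume
estimators and normalized MI are deliberately out of scope.

A finite-sample caveat: with `n` samples and `b` bins the MI of
independent images is biased upward by roughly `(b-1)^2 / (2 n ln 2)`
bits; the independence test asserts MI below twice that bound.

## Composite cost and bending energy

The registration objective is `C(mu) = alpha1 * F + alpha2 * V` with
`F = -MI(A, B∘G_mu)` (negated so minimization maximizes similarity) and
`V` the bending energy: the mean over sampled voxel centers of

```
Φ = Gxx² + Gyy² + Gzz² + 2Gxy² + 2Gxz² + 2Gzy²
```

summed over displacement components — the squared Frobenius norm of the
displacement Hessian, zero exactly for affine fields. `V` is evaluated
from the analytic second derivatives; the tests compare it against a
brute-force per-voxel finite-difference loop.

**Weight scales.** MI is O(1) bits, while `Φ` for a few-millimetre field
on a ~16 mm lattice is O(10⁻⁴) mm²/mm⁴. `CostConfig` keeps a neutral
default `alpha1 = 1, alpha2 = 0.01` for standalone cost evaluation, but
the registration default is `alpha2 = 200` so the penalty actually
constrains the directions MI cannot see (below). A single-weight
formulation `C = F + λV` is available as `CostConfig.from_lambda`.

## Registration optimizer

Derivative-free, deterministic, multiresolution:

1. **Pyramid.** One level per entry of `grid_spacing_schedule`
   (default 16 mm then 8 mm), with factor-2 block-mean image
   downsampling at the coarser levels. Each level Gaussian-smooths the
   images (`smooth_sigma = 1` voxel) before computing MI: on
   piecewise-constant images the similarity otherwise carries no signal
   away from edges, and smoothing both widens the capture range and
   smooths the cost landscape. The fitted transform itself applies to the
   unsmoothed images.
2. **Global translation phase.** All control points move together with
   adaptive step halving — a bending-free mode that per-point moves
   cannot enter efficiently.
3. **Greedy coordinate descent.** Fixed scan order over control points;
   for each displacement component the best of {stay, +step, −step} is
   taken; when a full sweep improves the total cost by less than `tol`
   (relative), the step halves, from `step_init = 2 mm` down to
   `min_step = 0.05 mm`.
4. **Null-space parking.** Control points whose basis support contains no
   intensity-gradient voxel cannot affect the histogram; after each sweep
   they are set to the exact minimum of the bending energy given the rest
   (a Cholesky solve), accepted only if the total cost does not increase.
5. **Level transfer.** Each finer lattice is initialized by sampling the
   coarser field's displacement at the new control-point positions
   (exact for translations).

The accepted-move sequence makes the per-level cost trace non-increasing
by construction, and the whole procedure is bit-reproducible for fixed
inputs and configuration. Per-candidate evaluation is kept cheap by
precomputing dense (voxels × control points) B-spline weight matrices per
level, so a candidate costs one matrix product, one interpolation, and
one histogram.

**What recovery accuracy to expect.** On the 64×64 phantom with
ground-truth fields of up to 3 voxels, registration raises warped-mask
vertebra Dice from ≈0.9 to ≈0.98–0.99 on every seed and cuts the
vertebra-centroid mTRE to ≈0.2–0.4 of its initial value. The residual is
dominated by the aperture problem, not the optimizer: on a
piecewise-constant phantom the images constrain displacement only at
tissue edges and there only in the edge-normal direction, so the
tangential component at a vertebra centroid (≈18 voxels from the nearest
constraining corner) is recovered only through the bending prior, which
need not agree with a random ground-truth field. A least-squares oracle
given the exact normal-component displacement at every edge voxel — more
information than any intensity metric extracts — lands in the same
0.15–0.45 ratio range, which is why the toolkit does not chase a smaller
number by tuning.

## Phantoms

`generate_phantom` builds the gross geometry of a sagittal lumbar view:
`n_vertebrae` (default 5) axis-aligned super-ellipsoid bodies (exponent
4, blocky cross-section) stacked along the first axis, disc bands in the
gaps, and a vessel tube running parallel to the column. Intensities are
piecewise constant per tissue (background 20, vertebra 200, disc 120,
vessel 160, arbitrary units) with optional additive Gaussian noise —
reported noise on real scans is on a ~0.01–0.07 std/range scale, so the
"noisy condition" used in the experiments is `noise_sd = 10` (≈0.056 of
the dynamic range). Landmarks are the vertebral-body centroids.
Ground-truth deformations draw i.i.d. uniform control displacements in
`[-max, +max]` on a lattice spaced at a quarter of the image extent —
smooth, low-frequency fields the registration lattice can represent.
Every random operation derives its RNG stream from `(seed, operation
tag)`, so outputs are reproducible and independent across operations.

What the phantom does **not** emulate: MR sequence contrast, bias
fields, Rician noise statistics (additive Gaussian is a simplification),
partial-volume boundaries, pathology (stenosis grades), or anatomical
variability beyond the deformation model. Passing tests therefore
demonstrate the algorithms' internal correctness and their behaviour
under known geometric truth — not clinical-grade accuracy on patient
MRI.

## Segmenter

A numpy U-net: per level two 3×3 "same"-padded convolutions each followed
by ReLU; 2×2 max-pooling down, nearest-neighbour upsampling + a
channel-halving convolution + skip concatenation up; a 1×1 readout; depth
3, 8 base channels (~100k weights). "Same" padding replaces the classic
valid-convolution crop to keep shape bookkeeping trivial; the difference
is boundary-only. Softmax probabilities feed a soft-Dice loss
`1 - mean_fg (2Σpt + ε)/(Σp + Σt + ε)` with `ε = 1` for stability;
gradients are hand-derived (verified against finite differences in the
tests) and optimized with Adam at `1e-3` with step decay (halved every 4
epochs), batch 8, 12 epochs on 50 generator-varied slices — a couple of
minutes on one CPU.

Soft-Dice-only training at this scale is sensitive to initialization: a
minority of random inits settle into basins where part of the foreground
is never recovered and the training loss itself plateaus. Training
therefore restarts on plateau: if the epoch-mean loss is still above
0.12 after 5 probe epochs, that initialization is abandoned and the next
one is drawn from a seed derived as `(seed, attempt)`, up to 3 restarts
(the stuck-versus-converged loss gap is roughly an order of magnitude,
so the threshold is not delicate). The whole procedure — init, shuffling,
restarts — is a deterministic function of `seed`; the tests assert
identical weight hashes across runs. Inputs are globally standardized by the
training set's mean/std, stored with the model.

The phantom task is intensity-separable, so held-out hard Dice ≥ 0.95
(noise-free) and ≥ 0.90 (noisy) are expected and asserted; this measures
the training machinery, not real-MRI difficulty.

## Metrics

Dice and Jaccard are computed from voxel counts of a selected label
(`D = 2J/(1+J)` holds identically since both come from the same counts).
Conventions at the degenerate ends: both regions empty → 1 (perfect
agreement of empty sets); exactly one empty → 0. mTRE is the plain mean
of Euclidean landmark distances. The noise measure — std of ROI
intensities over the volume's dynamic range — is one reasonable
normalization among several; it is dimensionless and comparable across
images but is an interpretation, not a standard.

## Problem sizes

The shipped experiments use 64×64 2D phantoms, 10 registration seeds,
50 training / 10 held-out segmentation slices, 32×32 domains for the
brute-force bending oracle, and 10⁵ samples for the basis identity —
sizes chosen so the full battery runs on a single CPU in minutes while
still exercising every code path at meaningful scale.

## Known limitations

* 2D registration is the tested configuration; 3D code paths exist
  (transform, warp, metrics, phantom) but the optimizer has only
  smoke-level coverage in 3D at these problem sizes.
* No diffeomorphism guarantee: large control displacements can fold the
  field; the ground-truth generator stays in a smooth regime.
* The optimizer is local; initial misalignments beyond the coarse-level
  capture range (roughly the coarsest grid spacing) are not recovered.
* MI with 32 hard bins is a step-wise objective at sub-bin scales, which
  bounds achievable sub-voxel precision together with the aperture
  limit discussed above.
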