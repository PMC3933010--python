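# Methods

This note documents the model, the numerical choices behind each stage,
what the phantom generator emulates, and the package's known limitations.
Everything quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`.

## Model and assumptions

The organ is assumed smooth with approximately elliptic axial cross
sections. Each slice outline is the ellipse
ρ = (θ₁, θ₂, α₁, α₂, φ) ∈ ℝ² × ℝ₊² × (−π/2, π/2]; a case is an ordered
stack of such ellipses at the contour slice positions. The best-fitting
ellipse minimizes the summed squared *orthogonal* distances of the manual
contour points to the boundary (total least squares in the plane). This is
deliberately less expressive than meshes or medial representations: the
goal is an interpretable, near-instant initial delineation, not a perfect
segmentation. On contours that truly depart from the ellipse family the
per-slice residual is the model mismatch, which the bumpy phantom mode
makes measurable.

Statistics live in a sample space reached by a similarity-type
control-point transform (translation, one in-plane rotation, one isotropic
in-plane scale, one z-scale). A similarity map keeps ellipses ellipses,
which any anisotropic or nonlinear warp would not; that closure is why the
transform family is restricted. Slice centers are parametrized as offsets
η from the center curve ξ — the component-wise quadratic in z through the
three control-point group centroids — so the learned mean shape stays
anchored to the user's clicks. Absolute-center statistics are estimated
and stored as well (`position_mode="theta"`), including the per-slice 3×3
covariance, though the default prior factorizes per component.

Distributional assumptions per slice: η and φ Gaussian, α log-normal (the
moments of a = log α are estimated, making positivity structural and the
prior mean a geometric mean). φ uses ordinary linear moments on the
unwrapped angle sequence; after de-rotation its variance is small, so a
circular distribution is unnecessary.

## Parameters that matter

| parameter | default | units | meaning / why |
|---|---|---|---|
| `L` | 11 | slices | canonical slice count; near the population mean contour count (~10.5) so resampling is mild in both directions |
| `circ_threshold` | 0.95 | ratio | circularity min(α)/max(α) above which φ is blended toward the neighbors' mean, weight (c − 0.95)/0.05; orientation is ill-determined for near-circles |
| `smooth_window` | 3 | slices | centered moving average of the unwrapped φ sequence, clipped at the ends; provably never increases the angle total variation |
| `band_mm` | 5 | mm | width of the outside shell for the gray-level model; wide enough to see background on both sides of a misplaced boundary |
| `n_iter` / `burn_in` | 20000 / 5000 | iterations | sampler defaults; experiments in this repo use 1500/500 at phantom scale, where chains equilibrate quickly |
| `proposal_scale` | 0.25 | × prior sd | initial random-walk scale per parameter |
| `target_accept` | 0.3 | — | burn-in adaptation target (see below) |
| control points | 6 × 3 slices | — | parametric angles 0°–300° on the first/center/last slices; centroids of 6 symmetric points coincide with the ellipse center, which makes the center curve exact for noiseless clicks |

## Numerical choices

**Point-to-ellipse projection.** In the ellipse frame, reduced to the
first quadrant, the foot of the orthogonal projection solves the monotone
scalar equation F(t) = (α₁p₁/(t+α₁²))² + (α₂p₂/(t+α₂²))² − 1 = 0 on
(−min(α)², ∞). A vectorized bisection (104 halvings, i.e. to machine
precision from a guaranteed bracket) is used instead of Newton for
unconditional robustness; points on the symmetry axes and the center take
their closed forms, and the center of a *circular* ellipse projects, by
convention, to the first-axis endpoint. Tests verify agreement with a
10⁶-point dense-sampling oracle to 1e−4 mm.

**Ellipse fitting.** Initialization is the numerically stable direct
algebraic least-squares fit constrained to ellipses (generalized
eigenproblem of the ellipse-specific scatter matrix, on centered/scaled
coordinates); refinement is Levenberg–Marquardt on the orthogonal-distance
residuals with α optimized as log α. Collinear input and non-elliptical
algebraic solutions raise typed errors; non-convergence returns the best
iterate with a warning rather than failing, and the refined objective is
asserted never to exceed the algebraic one.

**Axis reordering.** The center slice M = ⌈L/2⌉ is the basis; walking
outward, each slice takes whichever of its four equivalent representations
{(α₁,α₂,φ), (α₁,α₂,φ+π), (α₂,α₁,φ±π/2)} (mod 2π) is nearest in angle to
the processed neighbor. Since candidates are spaced π/2 apart the chosen
adjacent gap is ≤ π/4. Boundaries are provably unchanged; tests assert
this via projection distances ≤ 1e−9.

**Angle handling.** All smoothing/interpolation of φ happens on the
sequence unwrapped with period π (an unlabeled ellipse orientation is
π-periodic); at training time each case's sequence is shifted by a
multiple of π so its center-slice angle lies in (−π/2, π/2], making
sequences comparable across cases.

**Resampling.** Each parameter is an independent interpolating spline in
the normalized slice position t ∈ [0, 1] (not raw z, so cases with
different slice counts share a domain): not-a-knot cubic for ≥ 4 knots,
degrading to quadratic/linear below. Knots are reproduced exactly;
interpolated axis lengths are floored at 1e−6 mm with a warning.

**Transform conventions.** The in-plane rotation aligns the first
principal direction of the center-slice control group with the x-axis,
angle fixed to (−π/2, π/2]. The principal *direction* is sign-ambiguous,
so the convention is π-ambiguous for rotations that push the direction
across ±π/2; within a de-rotated clinical workflow orientations stay far
from the wrap. Declared, not inferred — see limitations.

**Deformation.** The sample-space mean shape is resampled to the number of
case slices spanned inclusively by the first/last control slices (no
extrapolation beyond the clicks), centers are set to ξ + μ_η at the case
slices' sample-space z, and everything is mapped back through the inverse
transform. The pipeline is an exact fixed point: a case whose normalized
stack equals the mean shape is reproduced from its own control points to
1e−6 (asserted).

**Likelihood and sampler.** The gray model is empirical-Bayes: inside and
shell voxel populations are estimated from the deformed template itself,
with sds floored at 1e−6 gray units and at 5% of the inside/outside
contrast so a noiseless region cannot produce a degenerate Gaussian that
lets one voxel dominate. For the chain, the joint gray-level density is
evaluated over a per-slice voxel set *frozen at chain start* (template
ellipse dilated by 2×band): each contained voxel is scored under the
inside Gaussian when the current ellipse covers it, else the outside one.
A state-dependent voxel set would make densities incomparable across
states and bias the chain toward small ellipses (fewer factors), which a
pilot showed catastrophically. The sampler is slice-blocked random-walk
Metropolis over (η₁, η₂, a₁, a₂, φ); per-slice proposal factors adapt
toward 30% acceptance during burn-in and are frozen afterwards, so the
sampling phase is a fixed-kernel chain. The posterior summary is the
parameter-wise posterior mean (α via mean of a, then exp); MAP over
visited states is available. The kernel itself is validated against direct
numerical integration of a 2-parameter toy posterior (total variation
< 0.05 at 10⁵ iterations).

**Degenerate statistics.** Zero-variance parameters (e.g. a model trained
on identical cases) use a point-mass convention in the prior density:
contribution 0 at the mean, −∞ elsewhere, never NaN.

**Evaluation.** Hausdorff distances are computed between point sets —
reference polylines densified uniformly in arc length to 360 points, model
ellipses sampled at 360 parametric points (doubling to 720 changes HD by
< 0.005 mm on the standard phantom). Masks for Dice/accuracy use the
pixel-center rule on the case's voxel grid; reference contours are filled
by the even-odd rule. Accuracy keeps its printed form
1 − (|FP|+|FN|)/(|TP|+|FN|), whose denominator is the reference volume, so
heavy over-segmentation legitimately drives it below 0. MAD is unscaled.

## The phantom generator

`PhantomSpec` defaults emulate the target acquisition: 288×288 grid at
0.559 mm, slice distance 3.3 mm, 6–15 contour slices per case (mean ~10.5),
mid-slice semi-axes 15–30 mm with end-tapered profiles, smooth per-case
center arcs plus a small smoothed random walk, a population orientation
(0.2 rad) with case- and slice-level variation, two-population gray levels
(200 vs 100, noise sd 10), 0.3 mm contour-point jitter and 1 mm
control-point jitter. In default mode the ground truth is exactly a stack
of ellipses (zero model mismatch), which separates fitting error from
model error; `bumpy=True` adds low-order angular radius perturbations
(3%/2% on harmonics 2 and 3) so the BFE itself leaves a measurable
residual, emulating real anatomy's departure from the ellipse family.

What it does **not** emulate: MR texture, bias fields, neighboring-organ
boundaries (bladder/rectum), observer-specific contouring styles, or
oblique acquisitions. Passing the synthetic acceptance thresholds
therefore demonstrates correctness of the machinery and plausible
statistical behavior under the stated geometry — not clinical-grade
performance; on real data the deformed mean shape is expected to be
noticeably further from manual contours than on these phantoms.

Experiment sizes in the tests and the acceptance script (33 cases, 23/10
splits, 10 split replicates, 10 refinement runs at 1500 iterations,
populations of 4–8 cases for unit tests) were chosen as the smallest
designs that make the statistical assertions sharp.

## Known limitations

- The π-ambiguity of the principal-direction convention (above): two cases
  differing by an in-plane rotation near ±π/2 can normalize to sample-space
  stacks differing by a half-turn. Irrelevant after de-rotation, but a
  labels-based convention would remove it.
- The circularity relaxation is a one-pass blend toward the neighbors'
  input angles; it is not idempotent for chains of consecutive
  near-circular slices (a fixed-point iteration would be).
- Deformation assumes (near-)equidistant case slices when matching
  resampled canonical positions to case slices; strongly non-uniform slice
  grids would need interpolation at the exact normalized positions of each
  slice (the machinery exists in `correspondence.interpolate_stack`).
- The likelihood ignores in-plane partial-volume effects (pixel-center
  classification) and models gray levels as two homogeneous Gaussians.
- RT-STRUCT files are not parsed; contours, control points, stacks and
  models travel as the package's versioned JSON documents (volumes as
  NRRD/NIfTI/DICOM series).
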