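# Methods

This note documents the models implemented in `edgereg`, the numerical
choices behind them, the synthetic evaluation protocol, and the known
limitations.

## TV-L1 decomposition and scale space

The cartoon/texture split minimizes `TV(I) + λ ∫|I − I₀|`.  The L1 (not
L2) fidelity is what makes the model *contrast-invariant* and gives it the
geometric selection law: for a disk of radius `r` and amplitude `c₁`, the
solution is `0` for `λ < 2/r` and the full disk for `λ > 2/r`, independent
of `c₁`; at exactly `λ = 2/r` the solution set is `{s·1_disk : 0 ≤ s ≤ c₁}`
and the solver returns the minimal member (`s = 0`).  For nested disks the
components peel strictly by size as `λ` decreases.  These laws, not any
smoothing heuristic, are what the multiscale registration builds on.

### Discretization and solver

Intensities are normalized to [0, 1] before decomposition and `λ` is
interpreted on that scale, so schedules transfer across modalities; outputs
are mapped back, and `texture = input − cartoon` holds to the last ulp.

The default solver uses the level-set (coarea) structure of the energy:
after quantization to `levels` gray values (default 256; the registration
pipeline uses 32), each threshold's upper level set independently solves a
binary problem `min_S Per_w(S) + λ·vol·|S xor F|`, which is a source/sink
min-cut.  Solutions are nested across thresholds (enforced explicitly
against rounding ties) and stack into the exact global minimizer of the
quantized energy — verified in the tests by exhaustive enumeration on
binary 3×3 instances.

The discrete perimeter `Per_w` uses, in 2D, the 8-neighborhood with
Cauchy–Crofton angular weights `w_k = cell·Δφ_k / (2|e_k|)` (the
orientation bias of the cut metric averages out around closed contours, so
disk thresholds land at `2/r` to within a few percent); in 3D, the
6-neighborhood with face-area weights (anisotropic spacing enters both the
edge weights and the volume term).  Min-cuts are solved with integer
capacities (adaptive scaling, well inside int64) via
`scipy.sparse.csgraph.maximum_flow`; the minimal source-side set is taken,
which implements the `s = 0` tie-break.

Volumes beyond a configurable node cap (default 2·10⁶) fall back to a
Chambolle–Pock primal–dual iteration with the exact L1 proximal map
(soft shrinkage toward the input), forward-difference isotropic TV, step
sizes `τ = σ = 1/L`, stopping at 10⁻⁴ relative energy change or 500
iterations.  The fallback is approximate (a few percent L1 error on disk
phantoms) and uses a different TV stencil than the graph; optimality
guarantees apply to the graph solver only.

Degenerate cases: `λ = 0` has no data term; the solver returns the median
constant by convention.  Constant inputs return themselves.

## B-spline FFD

Deformations are displacement fields parameterized by cubic tensor-product
B-splines on a regular control grid (one coefficient vector in mm per
control point; grids are placed with a two-knot margin beyond the image).
Key exactness properties, each tested to tight tolerance: partition of
unity (uniform translations are reproduced to < 10⁻¹⁰), locality
(perturbing one control point changes nothing outside its 4-knot-span
support), and refinement (halving the spacing by the subdivision masks
`(c_{i−1}+6c_i+c_{i+1})/8`, `(c_i+c_{i+1})/2` preserves the represented
field to < 10⁻⁸ mm).  Refinement is separable and can be restricted to a
subset of axes; the registration does not refine an axis below 4 voxel
spacings, which keeps the degrees of freedom bounded on thin volumes where
halving the through-slice axis would add parameters without information.

## NMI and the level optimizer

Similarity is Studholme's normalized mutual information
`(H(A)+H(B))/H(A,B)` (entropies in bits) over a B×B joint histogram with
hard linear binning, B = 32 by default, over each image's robust intensity
range (0.5–99.5 percentiles, which also keeps salt-and-pepper outliers out
of the bin range).  Only samples whose warp target lies inside the moving
image enter the histogram.  NMI ∈ [1, 2]; identical images score 2,
independent ones 1.

Each resolution level maximizes NMI over the FFD coefficients by
deterministic coordinate ascent: sweeps over the active control points try
±step moves per component, tracking the *exact* global NMI change through
incremental joint-histogram updates restricted to the point's support.
A move is accepted only if NMI strictly improves, so the per-level trace is
monotone by construction.  The step starts at 2 mm times the level's
subsampling factor and halves whenever a sweep accepts nothing, with one
annealing restart from half the initial step; the level stops at the sweep
cap (default 20–25) or when the step falls below 0.05 mm.  Active control
points are those whose support touches a fixed-image gradient above 0.5% of
the maximum; the rest keep their coarse-level values.  The effective bin
count is capped at `sqrt(N/6)` so sparse coarse-level histograms cannot
saturate NMI at 2.

Two deliberate choices here: (1) coordinate ascent with exact local updates
replaced gradient ascent on finite differences — the hard-binned objective
is piecewise constant, and secant gradients through it proved too noisy to
drive the optimization reliably; (2) an optional first-order Parzen
(linear) soft binning of the warped intensity (`parzen=True`) smooths the
objective further, but makes the identity transform a non-optimum for
identical images (the smoothed histogram rewards off-grid sampling), so
hard binning remains the default.

## Multiscale registration

Stage 1 builds the TV-L1 pyramids of both images, each with its own λ
schedule (planning-CT and CBCT intensity scales differ; after
normalization the same schedule is usually fine and is the default in the
tools).  Stage 2 iterates levels coarse → fine: subsample the level's
cartoons (anti-aliased, per-axis factors), optimize the control grid,
then refine the grid to seed the next level.  The finest level registers
the original images by default (`use_original_at_finest`), since λ₁
retains nearly all structure; set it to False to register cartoons
throughout, e.g. when the finest cartoon is a denoised image.  The NFFD
baseline is the identical loop with the decomposition disabled.  The
default grid schedule starts at ~1/4 of the image extent per axis and
halves per level, subject to the 4-voxel floor above.

## Automated λ selection

The selection assumes the optimal λ is a property of the image class, not
of the transformation model, so it is estimated with rigid transforms
only and reused for deformable registration.  Known transforms are
implanted on the floating image by resampling with the *inverse* map, so
the registration estimate is directly comparable to the implanted
parameters.  Each candidate λ is scored by the offset — weighted L1
parameter error with κ = (1, 1, 1, 180/π, 180/π, 180/π), making 1° ≡ 1 mm —
averaged over pairs × transforms; the argmin wins, ties going to the larger
λ (finer structure retained).  Levels are chosen greedily coarse-of-schedule
downward, each level decomposing the previous level's chosen cartoon;
candidates not below the previous level's λ are skipped with a warning, and
a failed registration scores +∞.  Rotations are about the volume centre
(the rotation centre is a convention, not part of the model).  Selected
schedules are cached by (modality, anatomy, size class) with
lookup-before-optimize; the granularity of the size class is the caller's
choice.

## Synthetic protocol and what it shows

No clinical data ship with the package; all inputs are generated:

* **Phantoms** — sums of disk/ellipsoid indicators plus an optional smooth
  random background texture.  The `thorax_phantom_spec` used in the
  recovery experiment has a body ellipsoid filling most of the FOV, two
  organs of different sizes, two small high-contrast markers, and texture
  at ~5% of the intensity range, so structure exists at every
  decomposition scale and gradients cover most of the volume.
* **CBCT simulation** — linear gray transform `a·I + b`, then Gaussian
  noise (default σ = 2% of the transformed range) and salt-and-pepper
  noise (default 0.5% of voxels to the low/high values).  With noise off
  the simulation is exactly affine, and NMI against the original is 2 with
  aligned bins.
* **Known deformations** — random cubic-spline fields rescaled to a stated
  maximum shift, purely in-plane and identical on every slice (volumes are
  deformed slice by slice), with severity presets D1 < D2 < D3 at 4/7/10 mm
  maxima, all capped at 10 mm.  Same seed ⇒ proportional fields, so the
  ordering holds for every seed.

The recovery experiment runs on a 64×64×8 volume at 1×1×3 mm — a size
chosen so the whole protocol (two methods × three seeds) completes in a few
minutes on one CPU.  Two scaling choices matter and were made on
fidelity grounds:

* the known field's control spacing is 64 mm (the FOV scale): a ~10 mm
  maximum shift on a clinical volume varies smoothly across the patient,
  and the miniature must preserve that ratio — with several deformation
  lobes packed inside one patient diameter, the truth outside the body is
  not inferable from image content and the DD is dominated by
  unregistrable air;
* the λ schedule is (4.0, 3.0, 2.5) on normalized intensities — the
  *edge-protection* regime in which every level keeps all anatomy and
  progressively removes noise and fine texture.  Organ-selecting schedules
  (coarsest level = body outline only) leave the coarse registration with
  a single closed contour, whose tangential (aperture) ambiguity actively
  corrupts the coarse solution.  On slab-shaped volumes the 3D survival
  thresholds are dominated by the slice-thickness faces
  (λ* ≈ surface/volume, not 2/r), which is why the slab uses CBCT-like
  3 mm slices and why 2D in-plane intuition must not be applied blindly
  to thin 3D stacks.

At these conditions the edge-preserving method recovers the deformation to
DD ≈ 0.3–0.5 mm and is on average more accurate than the plain FFD
baseline (≈ 0.6 mm); both the sub-millimetre level and the ordering match
what the method reports on clinical data.  What the synthetic protocol
does *not* exercise: real CBCT physics (scatter, beam hardening, cupping
and other low-frequency artifacts — the simulation's noise is spatially
white), truly multimodal intensity relations (the gray transform is
affine), sliding organ interfaces, and anatomies where structures appear
in one image but not the other.  Passing it shows the machinery is correct
and the multiscale design sound at desk scale, not clinical performance.

## Conventions and degenerate inputs

Arrays are indexed (x, y[, z]) with world = origin + index·spacing, mm
everywhere, axis-aligned frames only (readers normalize from disk layout
and reject non-identity direction matrices).  Warping is pull-back:
`out(p) = moving(p + v(p))`, linear interpolation by default, padding value
configurable (default 0), out-of-bounds samples excluded from similarity.
Masks are voxel grids (values {0,1}); dose is transferred by plain
interpolation without Jacobian/mass correction.  DVH curves are cumulative
normalized volume, monotone non-increasing from 1.0 at zero dose to 0
beyond the maximum.  Volumetric overlap reports both |A∩B|/|A∪B| and
|A∩B|/|B|, since "overlap" alone is ambiguous.

## Known limitations

* No folding prevention or smoothness penalty on the FFD: large steps on
  weakly constrained regions can produce locally non-invertible fields.
* The coordinate-ascent optimizer is deterministic but greedy; it can stop
  in local NMI optima, and run-to-run accuracy on hard cases depends on
  the step schedule.
* The graph TV-L1 solver's memory grows with voxels × neighborhood; full
  clinical volumes at 256 gray levels should use the primal–dual fallback
  or coarser quantization.
* Rigid registration uses a Powell search from the identity; it is not
  robust to initial offsets much larger than the dominant structures.
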