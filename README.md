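# edgereg

Edge-preserving multiscale deformable registration for planning-CT /
cone-beam-CT (CBCT) adaptive radiotherapy, built on TV-L1 scale-space
decomposition, multilevel B-spline free-form deformation (FFD), and
normalized mutual information (NMI).

## The problem

Adaptive image-guided radiotherapy updates contours, dose and plan from the
CBCT acquired in the treatment room each day.  That requires deformable
registration between the high-quality planning CT and the noisy,
low-contrast daily CBCT.  Intensity-based NMI registration is the standard
multimodal tool, but CBCT noise and artifacts corrupt the joint histogram
and the optimization is easily trapped.

`edgereg` addresses this by registering *edge-preserving scale-space
representations* of both images instead of (or in addition to) the raw
intensities.  The decomposition is the TV-L1 model

    E(I; λ) = ∫ |∇I| dx + λ ∫ |I − I₀| dx,

which splits the input `I₀` into a cartoon `I(λ)` (piecewise smooth, edges
intact) and a texture `V(λ) = I₀ − I(λ)`.  Unlike Gaussian smoothing, TV-L1
selects structure by **geometric size, not contrast**: a disk of radius `r`
survives in the cartoon iff `λ > 2/r`.  Iterating with a decreasing
schedule `λ₁ > λ₂ > … > λ_m` gives a hierarchical scale space

    I₀ = I(λ_m) + Σᵢ V(λᵢ),

whose coarse levels keep only the large contours — exactly the structure
strong enough to drive a coarse FFD grid — while noise and small texture
are peeled off.  Registration then proceeds coarse to fine: optimize a
coarse control grid on the coarsest cartoons under NMI
(`NMI(A;B) = (H(A)+H(B))/H(A,B)`), up-sample the grid exactly (cubic
B-spline subdivision), and repeat at the next finer scale.  This is the
edge-preserving FFD (EFFD); the same loop on raw images is the plain
baseline (NFFD).

Also included:

* **Automated λ selection** — implant known rigid transforms on training
  pairs, decompose at candidate λ, rigid-register, and minimize the
  *offset* Σ κₙ|ρₙ′ − ρₙ| with weights (1, 1, 1, 180/π, 180/π, 180/π), so a
  1° rotation error counts as 1 mm.  Results are cached per
  (modality, anatomy, size class).
* **Synthetic evaluation protocol** — phantoms, simulated CBCT
  (`a·I + b` + Gaussian + salt-and-pepper noise), known spline displacement
  fields with a 10 mm maximum shift, and the deformation difference
  `DD = (1/N) Σ ‖Wᵢ − Kᵢ‖` in mm.
* **Adaptive-RT layer** — warp structure masks and dose grids through the
  deformation map, volumetric overlap, cumulative DVH curves.

The TV-L1 solver quantizes intensities and solves one binary min-cut per
gray-level threshold (the level-set formulation of the model), which gives
the *global* minimum of the discretized energy; a Chambolle–Pock
primal–dual iteration covers volumes too large for the graph.

## Worked example

`examples/02_register_synthetic_pair.py` builds a 64×64×8 thorax-like
phantom at 1×1×3 mm, simulates a CBCT from it, deforms the phantom by a
known smooth in-plane field (10 mm maximum shift) and registers with both
methods:

```
volume (64, 64, 8) at (1.0, 1.0, 3.0) mm, true field: mean 6.89 mm, max 10.00 mm
  level 2 (lambda=2.5): NMI 1.1392 -> 1.5729
  level 1 (lambda=3.0): NMI 1.5550 -> 1.6057
  level 0 (lambda=4.0): NMI 1.4088 -> 1.4682
EFFD DD = 0.336 mm   NFFD DD = 0.796 mm
```

The per-level lines show the NMI similarity rising monotonically within
each scale (coarse level 2 → fine level 0).  The deformation difference DD
is the mean voxel-wise error against the known field: the edge-preserving
method recovers a deformation averaging ~7 mm to a third of a millimetre,
about half the error of the plain FFD baseline on the same pair.

The other examples demonstrate the scale-space disk law
(`01_scale_space.py`), automated λ selection (`03_lambda_estimation.py`),
and contour/dose transfer with DVH (`04_contour_dose_transfer.py`).

A thin CLI mirrors the library:

```bash
edgereg decompose --in img.nii.gz --lambdas 0.26,0.17,0.1 --out-prefix scale_
edgereg register --fixed pct.nii.gz --moving cbct.nii.gz --levels 3 \
    --lambdas-fixed 2.5,0.5,0.25 --out-field disp.mha --out-warped warped.nii.gz
edgereg simulate --in pct.nii.gz --preset D2 --seed 7 --out-cbct cbct.nii.gz --out-field truth.mha
edgereg evaluate --calc disp.mha --truth truth.mha
edgereg dvh --dose dose.nii.gz --mask ptv.nii.gz --out dvh.csv
edgereg transfer --field disp.mha --mask ptv.nii.gz --dose dose.nii.gz --out-prefix day1_
```

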