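"""Synthetic study inputs and evaluation metrics.

Generates the inputs of the known-ground-truth evaluation protocol:
disk/ellipsoid phantoms (the geometry the TV-L1 scale laws are stated for),
simulated CBCT images (a linear gray transform of the CT plus Gaussian and
salt-and-pepper noise — the contrast/noise gap between planning CT and
in-room CBCT), and smooth spline displacement fields with a known maximum
shift, applied in-plane slice by slice as in the original protocol.  All
generators are pure functions of (spec, seed).

The recovery metric is the deformation difference DD: the mean Euclidean
discrepancy (mm) between a computed and a known displacement field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import LatticeMismatchError
from .ffd import ControlPointGrid, evaluate_ffd, grid_for_image
from .image import DisplacementField, ScalarImage, same_lattice

__all__ = [
    "DiskPhantomSpec", "CbctSimSpec", "KnownDeformationSpec",
    "make_phantom", "simulate_cbct", "make_known_deformation",
    "known_deformation_preset", "DEFORMATION_PRESETS",
    "deformation_difference", "checkerboard",
]


@dataclass(frozen=True)
class DiskPhantomSpec:
    """Piecewise-constant phantom: a sum of disk/ellipsoid indicators.

    ``disks`` is a sequence of ``(center, radius, amplitude)`` with center in
    world mm and radius either a scalar (disk/sphere) or per-axis radii
    (ellipse/ellipsoid).  Overlapping shapes add.  ``texture_amplitude`` adds
    a smooth random background texture (grain size ``texture_grain_mm``).
    """

    shape: tuple[int, ...]
    spacing: tuple[float, ...] = None
    origin: tuple[float, ...] = None
    disks: tuple = ()
    texture_amplitude: float = 0.0
    texture_grain_mm: float = 4.0
    seed: int = 0

    def __post_init__(self):
        ndim = len(self.shape)
        sp = self.spacing if self.spacing is not None else (1.0,) * ndim
        og = self.origin if self.origin is not None else (0.0,) * ndim
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in sp))
        object.__setattr__(self, "origin", tuple(float(o) for o in og))


@dataclass(frozen=True)
class CbctSimSpec:
    """CBCT simulation: linear gray transform a*I + b, additive Gaussian
    noise (sigma in output intensity units), then salt-and-pepper noise
    replacing ``sp_fraction`` of the voxels with the low/high values.

    Defaults: sigma at 2% and salt-and-pepper at 0.5% of the transformed
    intensity range — a visible but registration-survivable corruption.
    Use ``sigma_frac``/``sp_fraction`` directly or override ``sigma`` with an
    absolute value.
    """

    a: float = 1.0
    b: float = 0.0
    sigma: float | None = None
    sigma_frac: float = 0.02
    sp_fraction: float = 0.005
    sp_low: float | None = None
    sp_high: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.sp_fraction < 1.0:
            raise ValueError("sp_fraction must be in [0, 1)")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.sigma_frac < 0:
            raise ValueError("sigma_frac must be >= 0")


@dataclass(frozen=True)
class KnownDeformationSpec:
    """Smooth random B-spline displacement with a stated maximum shift.

    Coefficients are drawn i.i.d. normal on a control grid of spacing
    ``grid_spacing_mm`` and the realized field is rescaled so its maximum
    magnitude equals ``target_max_mm`` (always <= ``cap_mm``).  With
    ``slicewise`` (default) the field is purely in-plane and identical on
    every slice, matching the protocol of deforming 3D volumes slice by
    slice with a 2D field.
    """

    grid_spacing_mm: float = 24.0
    target_max_mm: float = 10.0
    cap_mm: float = 10.0
    slicewise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.target_max_mm > self.cap_mm:
            raise ValueError("target_max_mm exceeds cap_mm")
        if self.cap_mm == 0 and self.target_max_mm > 0:
            raise ValueError("cap is zero but nonzero shifts requested")


# three severities, all capped at a 10 mm maximum shift
DEFORMATION_PRESETS = {"D1": 4.0, "D2": 7.0, "D3": 10.0}


def make_phantom(spec: DiskPhantomSpec) -> ScalarImage:
    """Rasterize the phantom; values are exact sums of the shape amplitudes
    (texture, if any, is added on top)."""
    ndim = len(spec.shape)
    axes = [spec.origin[a] + spec.spacing[a] * np.arange(spec.shape[a])
            for a in range(ndim)]
    grids = np.meshgrid(*axes, indexing="ij")
    data = np.zeros(spec.shape)
    lo = np.asarray(spec.origin)
    hi = np.asarray([ax[-1] for ax in axes])
    for center, radius, amplitude in spec.disks:
        center = np.atleast_1d(np.asarray(center, dtype=float))
        radii = np.atleast_1d(np.asarray(radius, dtype=float))
        if radii.size == 1:
            radii = np.full(ndim, radii[0])
        if np.any(radii <= 0):
            raise ValueError("radii must be > 0")
        if np.any(center - radii < lo) or np.any(center + radii > hi):
            raise ValueError(f"disk at {tuple(center)} extends out of bounds")
        r2 = sum(((g - c) / r) ** 2
                 for g, c, r in zip(grids, center, radii))
        data += amplitude * (r2 <= 1.0)
    if spec.texture_amplitude:
        rng = np.random.default_rng(spec.seed)
        noise = rng.standard_normal(spec.shape)
        sig = [spec.texture_grain_mm / s for s in spec.spacing]
        tex = ndimage.gaussian_filter(noise, sig, mode="nearest")
        peak = np.abs(tex).max()
        if peak > 0:
            data += spec.texture_amplitude * tex / peak
    return ScalarImage(data, spec.spacing, spec.origin)


def simulate_cbct(pct: ScalarImage, spec: CbctSimSpec) -> ScalarImage:
    """Simulated CBCT = Gray_Trans(CT) + Noise(CT); seeded, reproducible."""
    rng = np.random.default_rng(spec.seed)
    out = spec.a * pct.data + spec.b
    lo = float(out.min()) if spec.sp_low is None else spec.sp_low
    hi = float(out.max()) if spec.sp_high is None else spec.sp_high
    sigma = spec.sigma
    if sigma is None:
        sigma = spec.sigma_frac * max(hi - lo, 0.0)
    if sigma > 0:
        out = out + rng.normal(0.0, sigma, out.shape)
    if spec.sp_fraction > 0:
        n = out.size
        k = int(round(spec.sp_fraction * n))
        idx = rng.choice(n, size=k, replace=False)
        salt = rng.random(k) < 0.5
        flat = out.reshape(-1)
        flat[idx[salt]] = hi
        flat[idx[~salt]] = lo
        out = flat.reshape(out.shape)
    return pct.with_data(out)


def make_known_deformation(spec: KnownDeformationSpec,
                           lattice: ScalarImage | DisplacementField
                           ) -> DisplacementField:
    """Known smooth displacement on an image lattice.

    The base draw depends only on the seed and grid, so two specs differing
    only in ``target_max_mm`` yield proportional fields (the severity
    presets are strictly ordered for every seed).
    """
    ndim = lattice.ndim
    inplane = ScalarImage(np.zeros(lattice.shape[:2]), lattice.spacing[:2],
                          lattice.origin[:2]) \
        if (ndim == 3 and spec.slicewise) else None
    target_geom = inplane if inplane is not None else lattice
    grid = grid_for_image(target_geom, spec.grid_spacing_mm)
    rng = np.random.default_rng(spec.seed)
    coeff = rng.standard_normal(grid.coefficients.shape)
    fld2 = evaluate_ffd(grid.with_coefficients(coeff), target_geom)
    vec = fld2.vectors
    peak = np.sqrt((vec ** 2).sum(-1)).max()
    if peak > 0:
        vec = vec * (spec.target_max_mm / peak)
    else:
        vec = np.zeros_like(vec)
    if inplane is not None:
        full = np.zeros(lattice.shape + (3,))
        full[..., :2] = vec[:, :, None, :]
        vec = full
    elif ndim == 3:
        pass  # full 3D draw (slicewise=False on a 3D lattice)
    return DisplacementField(vec, lattice.spacing, lattice.origin)


def known_deformation_preset(name: str, lattice, seed: int = 0,
                             grid_spacing_mm: float = 24.0,
                             slicewise: bool = True) -> DisplacementField:
    """The D1 < D2 < D3 severity presets (max shifts 4/7/10 mm, cap 10 mm)."""
    try:
        target = DEFORMATION_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; "
                         f"choose from {sorted(DEFORMATION_PRESETS)}") from None
    spec = KnownDeformationSpec(grid_spacing_mm=grid_spacing_mm,
                                target_max_mm=target, cap_mm=10.0,
                                slicewise=slicewise, seed=seed)
    return make_known_deformation(spec, lattice)


def thorax_phantom_spec(shape=(64, 64, 8), spacing=(1.0, 1.0, 1.0),
                        seed: int = 0) -> DiskPhantomSpec:
    """A thorax-like test object: a large body ellipsoid containing organs
    of several geometric sizes plus a smooth background texture, so that
    structures exist at every decomposition scale and image gradients cover
    most of the field of view."""
    shape = tuple(int(n) for n in shape)
    spacing = tuple(float(s) for s in spacing)
    ext = [(n - 1) * s for n, s in zip(shape, spacing)]
    c = [e / 2.0 for e in ext]

    def rel(fx, fy, fz=None):
        if len(shape) == 2:
            return (fx * ext[0], fy * ext[1])
        return (fx * ext[0], fy * ext[1], (fz if fz is not None else 0.5)
                * ext[2])

    if len(shape) == 2:
        disks = (
            (rel(0.5, 0.5), (0.49 * ext[0], 0.46 * ext[1]), 1000.0),
            (rel(0.36, 0.42), (0.16 * ext[0], 0.18 * ext[1]), -300.0),
            (rel(0.66, 0.62), (0.12 * ext[0], 0.11 * ext[1]), 400.0),
            (rel(0.48, 0.72), 0.05 * ext[0], 500.0),
            (rel(0.68, 0.32), 0.04 * ext[0], -400.0),
        )
    else:
        zr = 0.495 * ext[2]
        disks = (
            (rel(0.5, 0.5), (0.49 * ext[0], 0.46 * ext[1], zr), 1000.0),
            (rel(0.36, 0.42), (0.16 * ext[0], 0.18 * ext[1], 0.95 * zr),
             -300.0),
            (rel(0.66, 0.62), (0.12 * ext[0], 0.11 * ext[1], 0.85 * zr),
             400.0),
            (rel(0.48, 0.72), (0.05 * ext[0], 0.05 * ext[0], 0.7 * zr),
             500.0),
            (rel(0.68, 0.32), (0.04 * ext[0], 0.04 * ext[0], 0.6 * zr),
             -400.0),
        )
    return DiskPhantomSpec(shape=shape, spacing=spacing, disks=disks,
                           texture_amplitude=80.0, texture_grain_mm=4.0,
                           seed=seed)


def make_registration_case(pct: ScalarImage, preset: str = "D3",
                           sim: CbctSimSpec | None = None, seed: int = 0,
                           grid_spacing_mm: float = 24.0):
    """Known-ground-truth registration problem from a planning image.

    The fixed image is the planning image deformed by a known smooth field
    (pull-back, so registering fixed against the simulated CBCT of the
    undeformed image should recover exactly that field); the moving image is
    the CBCT simulation.  Returns ``(fixed, moving, truth)``.
    """
    from .image import warp_image  # local import to avoid cycle noise
    truth = known_deformation_preset(preset, pct, seed=seed,
                                     grid_spacing_mm=grid_spacing_mm)
    fixed = warp_image(pct, truth, interp="linear", pad=0.0)
    if sim is None:
        sim = CbctSimSpec(a=0.9, b=50.0, seed=seed + 1)
    elif sim.seed == 0:
        sim = replace(sim, seed=seed + 1)
    moving = simulate_cbct(pct, sim)
    return fixed, moving, truth


def deformation_difference(calculated: DisplacementField,
                           known: DisplacementField) -> float:
    """DD = (1/N) * sum_i ||W_i - K_i||_2 over all voxels, in mm."""
    if not same_lattice(calculated, known):
        raise LatticeMismatchError("fields must share a lattice")
    diff = calculated.vectors - known.vectors
    return float(np.sqrt((diff ** 2).sum(-1)).mean())


def checkerboard(a: ScalarImage, b: ScalarImage, tiles: int) -> ScalarImage:
    """Alternating tiles from two images for visual registration checks.

    ``tiles`` is the number of tiles along the longest axis; tile parity
    (sum of per-axis tile indices) selects the source image.
    """
    if not same_lattice(a, b):
        raise LatticeMismatchError("checkerboard inputs must share a lattice")
    if tiles < 1:
        raise ValueError("tiles must be >= 1")
    size = max(1, int(np.ceil(max(a.shape) / tiles)))
    parity = np.zeros(a.shape, dtype=int)
    for ax in range(a.ndim):
        shp = [1] * a.ndim
        shp[ax] = -1
        parity = parity + (np.arange(a.shape[ax]) // size).reshape(shp)
    return a.with_data(np.where(parity % 2 == 0, a.data, b.data))
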