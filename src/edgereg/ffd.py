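"""Cubic B-spline free-form deformation (FFD).

A deformation is parameterized by displacement vectors (mm) attached to a
regular control-point grid; the dense field is the tensor-product cubic
B-spline interpolation of those coefficients.  Coefficients parameterize
displacement (not absolute position), so grids compose and refine trivially.
A coarse grid spacing models global deformation, a fine spacing local
deformation; halving the spacing between resolution levels is exact for
cubic B-splines (subdivision identity), which lets a coarse solution seed the
next finer level without changing the represented field.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CoverageError
from .image import DisplacementField, ScalarImage, read_field, write_field

__all__ = [
    "ControlPointGrid",
    "grid_for_image",
    "evaluate_ffd",
    "refine_grid",
    "cubic_bspline_weights",
    "write_grid",
    "read_grid",
]


def cubic_bspline_weights(t: np.ndarray) -> np.ndarray:
    """The four cubic B-spline basis values at fractional offset ``t`` in
    [0, 1); returns shape ``(4,) + t.shape``.  The weights sum to 1."""
    t = np.asarray(t, dtype=float)
    return np.stack([
        (1 - t) ** 3 / 6.0,
        (3 * t ** 3 - 6 * t ** 2 + 4) / 6.0,
        (-3 * t ** 3 + 3 * t ** 2 + 3 * t + 1) / 6.0,
        t ** 3 / 6.0,
    ])


@dataclass(frozen=True)
class ControlPointGrid:
    """Cubic B-spline FFD coefficients.

    ``coefficients`` has shape ``(n1, ..., nd, d)``: a displacement vector in
    mm per control point.  Control point ``i`` sits at world position
    ``origin + i * spacing`` (mm).  The spline order is fixed at cubic.
    """

    coefficients: np.ndarray
    spacing: tuple[float, ...]
    origin: tuple[float, ...]

    def __post_init__(self):
        coeff = np.asarray(self.coefficients, dtype=float)
        if coeff.ndim not in (3, 4) or coeff.shape[-1] != coeff.ndim - 1:
            raise ValueError(
                "coefficients must have shape (*grid, d) with d matching the "
                f"grid dimensionality; got {coeff.shape}")
        spacing = tuple(float(s) for s in np.atleast_1d(self.spacing))
        origin = tuple(float(o) for o in np.atleast_1d(self.origin))
        ndim = coeff.ndim - 1
        if len(spacing) == 1:
            spacing = spacing * ndim
        if len(origin) == 1:
            origin = origin * ndim
        if len(spacing) != ndim or len(origin) != ndim:
            raise ValueError("spacing/origin must match grid dimensionality")
        if any(s <= 0 for s in spacing):
            raise ValueError("grid spacing must be > 0")
        if any(n < 4 for n in coeff.shape[:-1]):
            raise ValueError("need at least 4 control points per axis")
        object.__setattr__(self, "coefficients", coeff)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return self.coefficients.ndim - 1

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.coefficients.shape[:-1]

    def with_coefficients(self, coeff: np.ndarray) -> "ControlPointGrid":
        return ControlPointGrid(coeff, self.spacing, self.origin)

    def grid_coords(self, geometry: ScalarImage | DisplacementField):
        """Continuous grid coordinates of the lattice voxel centres, one 1D
        array per axis (the lattice is axis-aligned, so they separate)."""
        return [(geometry.origin[a]
                 + geometry.spacing[a] * np.arange(geometry.shape[a])
                 - self.origin[a]) / self.spacing[a]
                for a in range(self.ndim)]

    def covers(self, geometry) -> bool:
        """Whether every lattice point has full 4-point spline support."""
        for a, u in enumerate(self.grid_coords(geometry)):
            n = self.grid_shape[a]
            if u.min() < 1.0 - 1e-9 or u.max() > n - 2 + 1e-9:
                return False
        return True


def grid_for_image(geometry, spacing_mm) -> ControlPointGrid:
    """A zero-displacement grid covering ``geometry`` with margin enough to
    survive several halving refinements."""
    spacing_mm = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    ndim = geometry.ndim
    if spacing_mm.size == 1:
        spacing_mm = np.full(ndim, spacing_mm[0])
    origin = []
    shape = []
    for a in range(ndim):
        h = float(spacing_mm[a])
        extent = geometry.spacing[a] * (geometry.shape[a] - 1)
        origin.append(geometry.origin[a] - 2.0 * h)
        shape.append(int(np.ceil(extent / h)) + 6)
    coeff = np.zeros(tuple(shape) + (ndim,))
    return ControlPointGrid(coeff, tuple(spacing_mm), tuple(origin))


def evaluate_ffd(grid: ControlPointGrid, geometry) -> DisplacementField:
    """Dense displacement (mm) of the FFD on an image lattice.

    ``geometry`` is anything with ``shape``/``spacing``/``origin`` (a
    ScalarImage or DisplacementField).  Raises CoverageError if any lattice
    point lacks full spline support.
    """
    if grid.ndim != geometry.ndim:
        raise CoverageError("grid and lattice dimensionality differ")
    if not grid.covers(geometry):
        raise CoverageError("lattice extends outside the control grid support")
    ndim = grid.ndim
    base, wts = [], []
    for u in grid.grid_coords(geometry):
        i0 = np.floor(u).astype(int)
        # keep the base cell valid at the exact upper boundary
        i0 = np.minimum(i0, np.array(grid.grid_shape[len(base)]) - 3)
        base.append(i0)
        wts.append(cubic_bspline_weights(u - i0))
    out = np.zeros(geometry.shape + (ndim,))
    for offs in np.ndindex(*(4,) * ndim):
        w = 1.0
        idx = []
        for a, o in enumerate(offs):
            shp = [1] * ndim
            shp[a] = -1
            w = w * wts[a][o].reshape(shp)
            idx.append((base[a] + o - 1).reshape(shp))
        out += w[..., None] * grid.coefficients[tuple(idx)]
    return DisplacementField(out, geometry.spacing, geometry.origin)


def write_grid(grid: ControlPointGrid, path) -> None:
    """Serialize a grid as a vector-valued MetaImage of coefficients plus a
    JSON sidecar (``<path>.json``) carrying spacing, origin and order."""
    write_field(DisplacementField(grid.coefficients, grid.spacing,
                                  grid.origin), path)
    with open(f"{path}.json", "w") as fh:
        json.dump({"spacing_mm": list(grid.spacing),
                   "origin_mm": list(grid.origin),
                   "spline_order": 3}, fh, indent=2)


def read_grid(path) -> ControlPointGrid:
    fld = read_field(path)
    sidecar = f"{path}.json"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)
        if meta.get("spline_order", 3) != 3:
            raise ValueError("only cubic grids are supported")
        return ControlPointGrid(fld.vectors, tuple(meta["spacing_mm"]),
                                tuple(meta["origin_mm"]))
    return ControlPointGrid(fld.vectors, fld.spacing, fld.origin)


def refine_grid(grid: ControlPointGrid,
                axes: Sequence[int] | None = None) -> ControlPointGrid:
    """Halve the grid spacing, preserving the represented deformation exactly
    (cubic B-spline subdivision: even points (c[i-1]+6c[i]+c[i+1])/8, odd
    points (c[i]+c[i+1])/2).

    ``axes`` restricts the refinement to a subset of axes (tensor-product
    subdivision is separable), e.g. to keep the through-slice resolution
    coarse on thin volumes.  Default refines all axes.
    """
    coeff = grid.coefficients
    ndim = grid.ndim
    if axes is None:
        axes = range(ndim)
    axes = sorted(set(int(a) for a in axes))
    if any(a < 0 or a >= ndim for a in axes):
        raise ValueError("axis index out of range")
    spacing = list(grid.spacing)
    origin = list(grid.origin)
    for a in axes:
        c = np.moveaxis(coeff, a, 0)
        n = c.shape[0]
        new = np.empty((2 * n - 3,) + c.shape[1:])
        # index j runs 1..2n-3 at positions origin + j*(spacing/2)
        new[1::2] = (c[1:-1] * 6 + c[:-2] + c[2:]) / 8.0   # j = 2i, i=1..n-2
        new[0::2] = (c[:-1] + c[1:]) / 2.0                 # j = 2i+1, i=0..n-2
        coeff = np.moveaxis(new, 0, a)
        origin[a] += spacing[a] / 2.0
        spacing[a] /= 2.0
    return ControlPointGrid(coeff, tuple(spacing), tuple(origin))
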