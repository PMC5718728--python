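"""Adaptive-radiotherapy application layer: recontouring, redosing, DVH.

A registration's deformation map provides a voxel-to-voxel mapping between
the planning CT and the daily CBCT, so structures delineated once on the
planning CT (organs, PTV, GTV) and the planned dose distribution can be
transferred automatically to the daily image, and dose-volume histograms
recomputed for plan adaptation.  Dose is transferred by plain pull-back
interpolation (no Jacobian/mass correction), matching direct transfer by
the deformation map; contours are handled as voxel masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import LatticeMismatchError
from .image import DisplacementField, ScalarImage, StructureMask, \
    same_lattice, warp_image

__all__ = ["DoseGrid", "DVHCurve", "warp_structure", "warp_dose",
           "compute_dvh", "overlap_fraction", "OverlapFractions"]

# dose distributions ride on the same scalar-lattice container
DoseGrid = ScalarImage


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram, normalized volume.

    ``volume_fraction[i]`` is the fraction of the structure receiving at
    least ``dose_gy[i]``; the curve starts at 1.0 at zero dose, is monotone
    non-increasing, and is 0 beyond the maximum dose.
    """

    dose_gy: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.dose_gy, dtype=float)
        v = np.asarray(self.volume_fraction, dtype=float)
        if d.shape != v.shape or d.ndim != 1:
            raise ValueError("dose_gy and volume_fraction must be equal-length"
                             " 1D arrays")
        if np.any(np.diff(d) <= 0):
            raise ValueError("dose edges must be strictly increasing")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("DVH must be monotone non-increasing")
        object.__setattr__(self, "dose_gy", d)
        object.__setattr__(self, "volume_fraction", v)

    def value_at(self, dose: float) -> float:
        """Volume fraction receiving >= ``dose`` (step interpolation)."""
        i = np.searchsorted(self.dose_gy, dose, side="right") - 1
        if i < 0:
            return 1.0
        return float(self.volume_fraction[i])


def warp_structure(mask: StructureMask, fld: DisplacementField,
                   method: str = "nearest") -> StructureMask:
    """Transfer a structure mask through the deformation map.

    ``method``: 'nearest' (default) or 'linear' with a 0.5 threshold; the
    output is binary either way.
    """
    if mask.ndim != fld.ndim:
        raise LatticeMismatchError("mask and field dimensionality differ")
    if method not in ("nearest", "linear"):
        raise ValueError("method must be 'nearest' or 'linear'")
    img = ScalarImage(mask.data.astype(float), mask.spacing, mask.origin)
    warped = warp_image(img, fld, interp=method, pad=0.0)
    return StructureMask((warped.data >= 0.5).astype(np.uint8),
                         fld.spacing, fld.origin, mask.label)


def warp_dose(dose: DoseGrid, fld: DisplacementField) -> DoseGrid:
    """Transfer a dose grid through the deformation map (linear pull-back;
    non-negativity is preserved)."""
    if np.any(dose.data < 0):
        raise ValueError("dose must be non-negative")
    return warp_image(dose, fld, interp="linear", pad=0.0)


def compute_dvh(dose: DoseGrid, mask: StructureMask,
                edges: np.ndarray | int = 100) -> DVHCurve:
    """Cumulative DVH of a structure.

    ``edges`` is either an explicit strictly increasing array of dose levels
    (Gy) or a bin count, in which case levels span 0 to just past the
    maximum structure dose (so the curve reaches 0).
    """
    if not same_lattice(dose, mask):
        raise LatticeMismatchError("dose and mask must share a lattice")
    sel = mask.data.astype(bool)
    if not sel.any():
        raise ValueError("empty structure mask")
    vals = dose.data[sel]
    if np.isscalar(edges) or np.ndim(edges) == 0:
        top = float(vals.max())
        step = top / (int(edges) - 1) if top > 0 else 1.0
        levels = np.linspace(0.0, top + step, int(edges) + 1)
    else:
        levels = np.asarray(edges, dtype=float)
    frac = np.array([(vals >= d).mean() for d in levels])
    return DVHCurve(levels, frac)


class OverlapFractions(NamedTuple):
    """Both common overlap definitions are reported, since 'overlap' is
    ambiguous: ``jaccard`` = |a&b|/|a|b|, ``over_b`` = |a&b|/|b|."""

    jaccard: float
    over_b: float


def overlap_fraction(a: StructureMask, b: StructureMask) -> OverlapFractions:
    """Volumetric overlap between two masks on the same lattice."""
    if not same_lattice(a, b):
        raise LatticeMismatchError("masks must share a lattice")
    av = a.data.astype(bool)
    bv = b.data.astype(bool)
    inter = float(np.logical_and(av, bv).sum())
    union = float(np.logical_or(av, bv).sum())
    if union == 0:
        raise ValueError("both masks are empty")
    over_b = inter / bv.sum() if bv.sum() else float("nan")
    return OverlapFractions(inter / union, over_b)
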