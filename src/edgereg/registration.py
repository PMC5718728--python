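"""Multiscale deformable registration: TV-L1 scale space + multilevel FFD.

The framework has two stages.  Stage 1 decomposes the fixed and moving
images into hierarchical TV-L1 scale spaces (one lambda schedule each, since
planning-CT and CBCT intensity scales differ).  Stage 2 registers coarse to
fine: the coarsest cartoons — which retain only the largest edges and
contours — drive a coarse FFD control grid toward the global deformation;
the optimum is then up-sampled (exact B-spline subdivision) to seed the next
finer level, where more detail and a finer grid gradually recover local
deformation.  Normalized mutual information is the similarity at every
level; accepted optimizer steps are monotone in NMI.

The plain single-representation baseline (NFFD) is the same coarse-to-fine
loop with the decomposition disabled; the edge-preserving variant is
conventionally called EFFD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import LatticeMismatchError, RegistrationError
from .ffd import ControlPointGrid, cubic_bspline_weights, evaluate_ffd, \
    grid_for_image, refine_grid
from .image import DisplacementField, ScalarImage, subsample
from .metrics import DEFAULT_BINS, bin_indices, robust_range
from .tvl1 import LambdaSchedule, build_scale_space

__all__ = ["MultiscaleConfig", "RegistrationResult", "optimize_level",
           "register_multiscale", "nffd_baseline"]


@dataclass(frozen=True)
class MultiscaleConfig:
    """Settings of the multiscale registration.

    Per-level sequences are indexed fine-to-coarse: entry 0 is the finest
    level (largest lambda, subsampling factor 1), the last entry the
    coarsest.  ``lambdas_fixed``/``lambdas_moving`` of None disables the
    decomposition (the NFFD baseline).  ``coarsest_grid_spacing`` of None
    picks ~1/4 of the image extent per axis; finer levels halve it.
    """

    levels: int = 3
    lambdas_fixed: tuple[float, ...] | None = None
    lambdas_moving: tuple[float, ...] | None = None
    subsample_factors: tuple[int, ...] | None = None  # default (1, 2, 4, ...)
    coarsest_grid_spacing: float | tuple[float, ...] | None = None
    bins: int = DEFAULT_BINS
    max_iterations: int = 20
    step_mm: float = 2.0
    min_step_mm: float = 0.05
    tol: float = 1e-5
    anneal_cycles: int = 2  # step-annealing restarts per level
    # optional soft (linear Parzen) binning of the warped intensity in the
    # level optimizer; the hard-binned default keeps the identity transform
    # an exact fixed point for identical images
    parzen: bool = False
    active_gradient_frac: float = 0.005
    use_original_at_finest: bool = True
    quant_levels: int = 32  # gray levels of the TV-L1 graph solver
    # an axis is not refined below this many voxel spacings: bounds the
    # degrees of freedom on thin axes (the flexibility/cost trade-off)
    min_grid_spacing_voxels: float = 4.0

    def factors(self) -> tuple[tuple[int, ...] | int, ...]:
        """Per-level subsampling factors (scalar or per-axis tuples)."""
        if self.subsample_factors is not None:
            f = tuple(tuple(int(x) for x in v) if np.ndim(v) else int(v)
                      for v in self.subsample_factors)
        else:
            f = tuple(2 ** i for i in range(self.levels))
        if len(f) != self.levels:
            raise ValueError("need one subsampling factor per level")
        maxima = [int(np.max(v)) for v in f]
        if any(b < a for a, b in zip(maxima, maxima[1:])):
            raise ValueError("factors must not decrease toward coarse levels")
        return f

    def schedule(self, which: str) -> LambdaSchedule | None:
        lams = self.lambdas_fixed if which == "fixed" else self.lambdas_moving
        if lams is None:
            return None
        sched = LambdaSchedule(tuple(lams))
        if len(sched) != self.levels:
            raise ValueError(f"lambdas_{which} must have one value per level")
        return sched


@dataclass(frozen=True)
class RegistrationResult:
    """Final transform plus the per-level optimization record."""

    grid: ControlPointGrid
    field: DisplacementField
    nmi_traces: tuple[tuple[float, ...], ...]  # coarse -> fine
    level_info: tuple[dict, ...]               # coarse -> fine

    @property
    def final_nmi(self) -> float:
        return self.nmi_traces[-1][-1]


def _nmi_from_flat_counts(counts: np.ndarray, bins: int) -> float:
    total = counts.sum()
    if total <= 0:
        return np.nan
    c = counts.reshape(bins, bins)
    pa = c.sum(1)
    pb = c.sum(0)

    def ent(x):
        p = x[x > 0] / total
        return -(p * np.log2(p)).sum()

    hab = ent(counts)
    if hab == 0.0:
        return 2.0
    return (ent(pa) + ent(pb)) / hab


class _LevelProblem:
    """NMI-over-FFD objective at one resolution level, with local
    joint-histogram updates for cheap per-control-point finite differences
    (perturbing a control point only touches its 4-knot-span support)."""

    def __init__(self, fixed: ScalarImage, moving: ScalarImage,
                 grid: ControlPointGrid, cfg: MultiscaleConfig):
        if fixed.ndim != moving.ndim:
            raise LatticeMismatchError("fixed/moving dimensionality differs")
        self.fixed = fixed
        self.moving = moving
        self.cfg = cfg
        # cap bins so sparse coarse-level histograms cannot saturate NMI
        self.bins = min(cfg.bins,
                        max(6, int(round(np.sqrt(fixed.data.size / 6.0)))))
        self.ndim = fixed.ndim
        self.msp = np.asarray(moving.spacing)
        self.a_range = robust_range(fixed.data)
        self.b_range = robust_range(moving.data)
        self.fa = bin_indices(fixed.data, *self.a_range, self.bins)
        # moving-voxel coordinate of each fixed voxel at zero displacement;
        # separable because both lattices are axis-aligned
        self.base = [(fixed.origin[a] + fixed.spacing[a]
                      * np.arange(fixed.shape[a]) - moving.origin[a])
                     / moving.spacing[a] for a in range(self.ndim)]
        self._prepare_support(grid)
        self._prepare_active(grid)

    # -- geometry of the control-point support --------------------------
    def _prepare_support(self, grid: ControlPointGrid):
        self.i0, self.w4, self.lohi = [], [], []
        for a, u in enumerate(grid.grid_coords(self.fixed)):
            i0 = np.minimum(np.floor(u).astype(int), grid.grid_shape[a] - 3)
            self.i0.append(i0)
            self.w4.append(cubic_bspline_weights(u - i0))
            n_cp = grid.grid_shape[a]
            lo = np.searchsorted(i0, np.arange(n_cp) - 2, side="left")
            hi = np.searchsorted(i0, np.arange(n_cp) + 1, side="right")
            self.lohi.append((lo, hi))

    def _support(self, cp: tuple[int, ...]):
        slices, weights = [], []
        for a, c in enumerate(cp):
            lo, hi = self.lohi[a][0][c], self.lohi[a][1][c]
            if hi <= lo:
                return None
            slices.append(slice(lo, hi))
            sel = np.arange(lo, hi)
            weights.append(self.w4[a][c - self.i0[a][sel] + 1, sel])
        w = weights[0]
        for wa in weights[1:]:
            w = np.multiply.outer(w, wa)
        return tuple(slices), w

    def _prepare_active(self, grid: ControlPointGrid):
        """Control points whose support touches a high-gradient fixed voxel;
        the rest keep their (refined) coarse-level values."""
        g = np.gradient(self.fixed.data, *self.fixed.spacing)
        gm = np.sqrt(sum(x ** 2 for x in np.atleast_1d(g)))
        thresh = self.cfg.active_gradient_frac * gm.max()
        high = (gm > thresh).astype(np.int64)
        # integral image for fast any-high-in-region queries
        S = high
        for a in range(self.ndim):
            S = np.cumsum(S, axis=a)
        S = np.pad(S, [(1, 0)] * self.ndim)
        self.active = []
        for cp in np.ndindex(*grid.grid_shape):
            sup = self._support(cp)
            if sup is None:
                continue
            slices, _ = sup
            total = 0
            for corner in itertools.product((0, 1), repeat=self.ndim):
                idx = tuple(sl.stop if c else sl.start
                            for sl, c in zip(slices, corner))
                total += ((-1) ** (self.ndim - sum(corner))) * S[idx]
            if total > 0:
                self.active.append(cp)

    # -- warping and similarity ------------------------------------------
    def _coords(self, vectors: np.ndarray, region=None):
        if region is None:
            region = tuple(slice(None) for _ in range(self.ndim))
        out = []
        for a in range(self.ndim):
            shp = [1] * self.ndim
            shp[a] = -1
            out.append(self.base[a][region[a]].reshape(shp)
                       + vectors[region + (a,)] / self.msp[a])
        return np.broadcast_arrays(*out)

    def _sample(self, coords):
        warped = ndimage.map_coordinates(self.moving.data, coords, order=1,
                                         mode="constant", cval=0.0)
        valid = np.ones(warped.shape, dtype=bool)
        for a in range(self.ndim):
            valid &= (coords[a] >= 0) & (coords[a] <= self.moving.shape[a] - 1)
        return warped, valid

    def _counts(self, fa, warped, valid):
        """Joint histogram contribution with first-order (linear) Parzen
        binning of the warped intensity: each sample is shared between its
        two adjacent bins, making NMI continuous in the displacement (a
        hard-binned objective is piecewise constant and stalls the search).
        The fixed-image axis stays hard-binned (it never moves)."""
        sel = valid
        lo, hi = self.b_range
        if not self.cfg.parzen:
            codes = (fa[sel] * self.bins
                     + bin_indices(warped[sel], lo, hi, self.bins))
            return np.bincount(codes, minlength=self.bins * self.bins
                               ).astype(float)
        b = (warped[sel] - lo) / (hi - lo) * self.bins - 0.5
        b = np.clip(b, 0.0, self.bins - 1.0)
        b0 = np.floor(b).astype(np.intp)
        b0 = np.minimum(b0, self.bins - 2)
        w1 = b - b0
        base = fa[sel] * self.bins + b0
        counts = np.bincount(base, weights=1.0 - w1,
                             minlength=self.bins * self.bins)
        counts += np.bincount(base + 1, weights=w1,
                              minlength=self.bins * self.bins)
        return counts

    def evaluate(self, grid: ControlPointGrid):
        vec = evaluate_ffd(grid, self.fixed).vectors
        coords = self._coords(vec)
        warped, valid = self._sample(coords)
        if not valid.any():
            raise RegistrationError("empty overlap between fixed and moving")
        counts = self._counts(self.fa, warped, valid)
        return vec, warped, valid, counts, _nmi_from_flat_counts(counts,
                                                                 self.bins)

    def sweep(self, coeff, vec, warped, valid, counts, current, step):
        """One coordinate-ascent pass over all active control points.

        Each control point's components are tried at +/- ``step`` mm; a move
        is accepted iff it strictly improves the global NMI, which is
        tracked exactly through incremental joint-histogram updates on the
        point's support region.  Mutates coeff/vec/warped/valid in place and
        returns (counts, current NMI, number of accepted moves).
        """
        moves = 0
        d = self.ndim
        for cp in self.active:
            region, w = self._support(cp)
            fa_r = self.fa[region]
            for comp in range(d):
                old_counts = self._counts(fa_r, warped[region],
                                          valid[region])
                coords_r = self._coords(vec, region)
                best = (current + self.cfg.tol, None)
                for sgn in (1.0, -1.0):
                    pert = list(coords_r)
                    pert[comp] = coords_r[comp] \
                        + sgn * step * w / self.msp[comp]
                    new_w, new_v = self._sample(pert)
                    cand_counts = counts - old_counts \
                        + self._counts(fa_r, new_w, new_v)
                    val = _nmi_from_flat_counts(cand_counts, self.bins)
                    if np.isfinite(val) and val > best[0]:
                        best = (val, (sgn, new_w, new_v, cand_counts))
                if best[1] is not None:
                    sgn, new_w, new_v, cand_counts = best[1]
                    coeff[cp + (comp,)] += sgn * step
                    vec[region + (comp,)] += sgn * step * w
                    warped[region] = new_w
                    valid[region] = new_v
                    counts = cand_counts
                    current = best[0]
                    moves += 1
        return counts, current, moves


def optimize_level(fixed: ScalarImage, moving: ScalarImage,
                   grid: ControlPointGrid, cfg: MultiscaleConfig
                   ) -> tuple[ControlPointGrid, list[float]]:
    """Maximize NMI(fixed, warp(moving)) over the FFD coefficients.

    Deterministic coordinate ascent: repeated sweeps over the active control
    points with per-component +/- trial moves at the current step size,
    halved whenever a sweep accepts nothing.  Every accepted move strictly
    improves NMI (monotone trace, one entry per improving sweep).  Returns
    the updated grid and the trace.
    """
    prob = _LevelProblem(fixed, moving, grid, cfg)
    vec, warped, valid, counts, current = prob.evaluate(grid)
    if not np.isfinite(current):
        raise RegistrationError("NMI non-finite at entry", trace=[current])
    trace = [current]
    coeff = grid.coefficients.copy()
    step = cfg.step_mm
    sweeps = 0
    cycles_left = max(1, cfg.anneal_cycles) - 1
    while sweeps < cfg.max_iterations:
        counts, current, moves = prob.sweep(coeff, vec, warped, valid,
                                            counts, current, step)
        sweeps += 1
        if not np.isfinite(current):
            raise RegistrationError("NMI became non-finite", trace=trace)
        if moves:
            trace.append(current)
        else:
            step /= 2.0  # anneal: finer moves once no +/- step helps
            if step < cfg.min_step_mm:
                if cycles_left == 0:
                    break
                cycles_left -= 1  # restart from a mid-size step
                step = max(cfg.step_mm / 2.0, cfg.min_step_mm)
    return grid.with_coefficients(coeff), trace


def _bounding_boxes_overlap(a: ScalarImage, b: ScalarImage) -> bool:
    for ax in range(a.ndim):
        a_lo = a.origin[ax]
        a_hi = a.origin[ax] + a.spacing[ax] * (a.shape[ax] - 1)
        b_lo = b.origin[ax]
        b_hi = b.origin[ax] + b.spacing[ax] * (b.shape[ax] - 1)
        if a_hi < b_lo or b_hi < a_lo:
            return False
    return True


def register_multiscale(fixed: ScalarImage, moving: ScalarImage,
                        cfg: MultiscaleConfig | None = None
                        ) -> RegistrationResult:
    """Two-stage edge-preserving multiscale registration.

    Stage 1 builds the TV-L1 pyramids of both images (their own lambda
    schedules).  Stage 2 iterates levels coarse to fine: subsample the
    level's cartoons, optimize the FFD grid, then refine the grid (spacing
    halved, field preserved) to seed the next level.  The finest level
    registers the original images by default, since the finest lambda
    retains nearly all structure.
    """
    cfg = cfg or MultiscaleConfig()
    if fixed.ndim != moving.ndim:
        raise LatticeMismatchError("fixed and moving dimensionality differ")
    if not _bounding_boxes_overlap(fixed, moving):
        raise RegistrationError("fixed and moving do not overlap in world "
                                "space")
    m = cfg.levels
    if m < 1:
        raise ValueError("levels must be >= 1")
    factors = cfg.factors()
    sched_f = cfg.schedule("fixed")
    sched_m = cfg.schedule("moving")

    def level_images(img: ScalarImage, sched: LambdaSchedule | None):
        if sched is None:
            return [img] * m
        pyr = build_scale_space(img, sched, levels=cfg.quant_levels)
        out = [pyr.cartoon(i) for i in range(m)]
        if cfg.use_original_at_finest:
            out[0] = img
        return out

    fixed_levels = level_images(fixed, sched_f)
    moving_levels = level_images(moving, sched_m)

    if cfg.coarsest_grid_spacing is not None:
        coarse_sp = cfg.coarsest_grid_spacing
    else:
        coarse_sp = tuple(max(e / 4.0, 2.0 * s)
                          for e, s in zip(fixed.extent, fixed.spacing))
    grid = grid_for_image(fixed, coarse_sp)

    traces, infos = [], []
    for i in range(m - 1, -1, -1):
        f_i = subsample(fixed_levels[i], factors[i])
        m_i = subsample(moving_levels[i], factors[i])
        # coarser levels take proportionally larger initial steps: the
        # coarse grid is responsible for the global deformation
        cfg_i = replace(cfg, step_mm=cfg.step_mm * int(np.max(factors[i])))
        grid, trace = optimize_level(f_i, m_i, grid, cfg_i)
        traces.append(tuple(trace))
        infos.append({
            "level": i,
            "lambda_fixed": sched_f[i] if sched_f else None,
            "lambda_moving": sched_m[i] if sched_m else None,
            "subsample_factor": factors[i],
            "grid_spacing_mm": grid.spacing,
            "nmi_start": trace[0],
            "nmi_end": trace[-1],
            "iterations": len(trace) - 1,
        })
        if i > 0:
            axes = [a for a in range(fixed.ndim)
                    if grid.spacing[a] / 2.0
                    >= cfg.min_grid_spacing_voxels * fixed.spacing[a]]
            if axes:
                grid = refine_grid(grid, axes=axes)
    return RegistrationResult(grid, evaluate_ffd(grid, fixed),
                              tuple(traces), tuple(infos))


def nffd_baseline(fixed: ScalarImage, moving: ScalarImage,
                  cfg: MultiscaleConfig | None = None) -> RegistrationResult:
    """Plain B-spline FFD baseline: the same coarse-to-fine loop on the raw
    intensity images (no scale-space decomposition)."""
    cfg = cfg or MultiscaleConfig()
    return register_multiscale(
        fixed, moving,
        replace(cfg, lambdas_fixed=None, lambdas_moving=None))
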