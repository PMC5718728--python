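"""Automated selection of the TV-L1 scale parameter.

The scale parameter lambda is inversely proportional to the geometric size
of the structures a decomposition level retains, so the optimal lambda is a
property of the image class (modality, anatomy, patient size), not of the
transformation model.  It can therefore be estimated once on well-registered
training pairs using *rigid* transforms only — implant known transforms (KT)
on the floating image, decompose both images at each candidate lambda,
rigid-register, and score the parameter error — and then reused for
deformable registration of all incoming datasets of the same type and size.

The score is the offset: a weighted L1 distance between true and estimated
rigid parameters with weights (1, 1, 1, 180/pi, 180/pi, 180/pi), so a 1
degree rotation error counts the same as a 1 mm translation error.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage, optimize

from .errors import RegistrationError
from .image import ScalarImage
from .metrics import DEFAULT_BINS, nmi_images
from .tvl1 import LambdaSchedule, solve_tvl1

__all__ = [
    "RigidParams", "OffsetWeights", "LambdaCandidateGrid",
    "DEFAULT_OFFSET_WEIGHTS", "offset", "apply_rigid", "implant_rigid",
    "rigid_register", "estimate_lambda", "LambdaEstimationResult",
    "LambdaCache",
]

logger = logging.getLogger(__name__)


def _wrap_angle(theta: float) -> float:
    """Wrap to (-pi, pi]."""
    t = (float(theta) + math.pi) % (2 * math.pi) - math.pi
    return math.pi if t == -math.pi else t


@dataclass(frozen=True)
class RigidParams:
    """Three translations (mm) and three rotations (radians).

    Rotations are about the volume centre, applied in the order
    ``Rx(theta1) @ Ry(theta2) @ Rz(theta3)``; for 2D images only ``tx``,
    ``ty`` and the in-plane rotation ``theta3`` are used.
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    theta1: float = 0.0
    theta2: float = 0.0
    theta3: float = 0.0

    def __post_init__(self):
        for name in ("tx", "ty", "tz", "theta1", "theta2", "theta3"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
            if name.startswith("theta"):
                v = _wrap_angle(v)
            object.__setattr__(self, name, v)

    def as_vector(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz,
                         self.theta1, self.theta2, self.theta3])

    @classmethod
    def from_vector(cls, v) -> "RigidParams":
        v = np.asarray(v, dtype=float)
        return cls(*v)

    def translation(self, ndim: int) -> np.ndarray:
        return self.as_vector()[:ndim]

    def rotation_matrix(self, ndim: int) -> np.ndarray:
        if ndim == 2:
            c, s = math.cos(self.theta3), math.sin(self.theta3)
            return np.array([[c, -s], [s, c]])
        c1, s1 = math.cos(self.theta1), math.sin(self.theta1)
        c2, s2 = math.cos(self.theta2), math.sin(self.theta2)
        c3, s3 = math.cos(self.theta3), math.sin(self.theta3)
        rx = np.array([[1, 0, 0], [0, c1, -s1], [0, s1, c1]])
        ry = np.array([[c2, 0, s2], [0, 1, 0], [-s2, 0, c2]])
        rz = np.array([[c3, -s3, 0], [s3, c3, 0], [0, 0, 1]])
        return rx @ ry @ rz


@dataclass(frozen=True)
class OffsetWeights:
    """Non-negative weights kappa_1..kappa_6 of the offset metric."""

    kappas: tuple[float, ...]

    def __post_init__(self):
        k = tuple(float(v) for v in self.kappas)
        if len(k) != 6 or any(v < 0 for v in k):
            raise ValueError("need 6 non-negative weights")
        object.__setattr__(self, "kappas", k)


# 1 degree of rotation error == 1 mm of translation error
DEFAULT_OFFSET_WEIGHTS = OffsetWeights((1.0, 1.0, 1.0) + (180.0 / math.pi,) * 3)


@dataclass(frozen=True)
class LambdaCandidateGrid:
    """Positive candidate lambdas per decomposition level."""

    per_level: tuple[tuple[float, ...], ...]

    def __post_init__(self):
        lv = tuple(tuple(float(v) for v in level) for level in self.per_level)
        if not lv or any(not level for level in lv):
            raise ValueError("each level needs at least one candidate")
        if any(v <= 0 for level in lv for v in level):
            raise ValueError("candidate lambdas must be positive")
        object.__setattr__(self, "per_level", lv)

    def __len__(self):
        return len(self.per_level)


def offset(true: RigidParams, est: RigidParams,
           weights: OffsetWeights = DEFAULT_OFFSET_WEIGHTS) -> float:
    """Weighted L1 parameter error in mm-equivalent units."""
    diff = np.abs(est.as_vector() - true.as_vector())
    return float(np.dot(np.asarray(weights.kappas), diff))


def _resample_affine(image: ScalarImage, R: np.ndarray, shift: np.ndarray,
                     interp: str = "linear", pad: float = 0.0) -> ScalarImage:
    """out(x) = image(R(x - c) + c + shift) with c the volume centre."""
    ndim = image.ndim
    c = np.asarray(image.origin) \
        + (np.asarray(image.shape) - 1) / 2.0 * np.asarray(image.spacing)
    axes = np.meshgrid(*image.world_axes(), indexing="ij")
    X = np.stack(axes, axis=-1)
    Y = (X - c) @ R.T + c + shift
    coords = (Y - np.asarray(image.origin)) / np.asarray(image.spacing)
    order = 1 if interp == "linear" else 0
    data = ndimage.map_coordinates(image.data, np.moveaxis(coords, -1, 0),
                                   order=order, mode="constant", cval=pad)
    return image.with_data(data)


def apply_rigid(image: ScalarImage, p: RigidParams,
                interp: str = "linear", pad: float = 0.0) -> ScalarImage:
    """Pull-back rigid resampling: rotation about the volume centre followed
    by translation, out(x) = image(R(x - c) + c + t)."""
    ndim = image.ndim
    return _resample_affine(image, p.rotation_matrix(ndim),
                            p.translation(ndim), interp, pad)


def implant_rigid(image: ScalarImage, p: RigidParams,
                  interp: str = "linear", pad: float = 0.0) -> ScalarImage:
    """Implant a known transform so that registering the result back to
    ``image`` recovers exactly ``p`` (resamples with the inverse map)."""
    ndim = image.ndim
    R = p.rotation_matrix(ndim)
    t = p.translation(ndim)
    return _resample_affine(image, R.T, -R.T @ t, interp, pad)


def rigid_register(fixed: ScalarImage, moving: ScalarImage,
                   bins: int = DEFAULT_BINS,
                   init: RigidParams | None = None,
                   maxiter: int = 400) -> RigidParams:
    """Rigid NMI registration (Powell search; rotations optimized in
    degrees so all parameters share the 1 mm == 1 degree scale)."""
    ndim = fixed.ndim
    n_par = 3 if ndim == 2 else 6
    b_range = None
    if moving.data.max() > moving.data.min():
        from .metrics import robust_range
        b_range = robust_range(moving.data)

    def to_params(v) -> RigidParams:
        if ndim == 2:
            return RigidParams(tx=v[0], ty=v[1], theta3=math.radians(v[2]))
        return RigidParams(v[0], v[1], v[2], math.radians(v[3]),
                           math.radians(v[4]), math.radians(v[5]))

    def objective(v):
        warped = apply_rigid(moving, to_params(v))
        try:
            return -nmi_images(fixed, warped, bins=bins, b_range=b_range)
        except ValueError:
            return 0.0  # empty overlap: worst similarity

    if init is None:
        x0 = np.zeros(n_par)
    elif ndim == 2:
        x0 = np.array([init.tx, init.ty, math.degrees(init.theta3)])
    else:
        x0 = np.concatenate([init.translation(3),
                             np.degrees(init.as_vector()[3:])])
    res = optimize.minimize(objective, x0, method="Powell",
                            options={"maxiter": maxiter,
                                     "xtol": 1e-3, "ftol": 1e-7})
    if not np.isfinite(res.fun):
        raise RegistrationError("rigid registration diverged")
    return to_params(res.x)


@dataclass(frozen=True)
class LambdaEstimationResult:
    """Chosen schedule plus the per-level candidate scores (mean offsets)."""

    schedule: LambdaSchedule
    scores: tuple[dict, ...]  # per level: {lambda: mean offset (mm-equiv)}


def estimate_lambda(pairs: Sequence[tuple[ScalarImage, ScalarImage]],
                    implanted: Sequence[RigidParams],
                    candidates: LambdaCandidateGrid | Sequence[Sequence[float]],
                    *, bins: int = DEFAULT_BINS, quant_levels: int = 64,
                    rigid_maxiter: int = 400,
                    weights: OffsetWeights = DEFAULT_OFFSET_WEIGHTS,
                    ) -> LambdaEstimationResult:
    """Greedy per-level lambda selection by exhaustive candidate sweep.

    For each level (coarse schedule built top-down), every candidate lambda
    is scored by decomposing both images of every training pair at that
    lambda, rigid-registering the decomposed pair for every implanted
    transform, and averaging the offset; the argmin wins (ties go to the
    larger lambda, which retains finer structure).  A candidate on which
    registration fails scores +inf and is logged.
    """
    if not isinstance(candidates, LambdaCandidateGrid):
        candidates = LambdaCandidateGrid(tuple(tuple(c) for c in candidates))
    if not pairs:
        raise ValueError("need at least one training pair")
    if not implanted:
        raise ValueError("need at least one implanted transform")

    # floating images with each KT implanted, decomposed progressively
    ref_chain = [ref for ref, _ in pairs]
    flo_chain = [[implant_rigid(flo, kt) for kt in implanted]
                 for _, flo in pairs]
    chosen: list[float] = []
    all_scores: list[dict] = []
    for level, cand_list in enumerate(candidates.per_level):
        scores: dict[float, float] = {}
        decomp_cache: dict[float, tuple] = {}
        for lam in sorted(set(cand_list)):
            if chosen and lam >= chosen[-1]:
                logger.warning("level %d: candidate %g >= previous level's "
                               "%g, skipped (schedule must decrease)",
                               level, lam, chosen[-1])
                continue
            refs_c = [solve_tvl1(r, lam, levels=quant_levels).cartoon
                      for r in ref_chain]
            flos_c = [[solve_tvl1(f, lam, levels=quant_levels).cartoon
                       for f in per_pair] for per_pair in flo_chain]
            total, count = 0.0, 0
            for p_i, (ref_c, per_pair) in enumerate(zip(refs_c, flos_c)):
                for kt, flo_c in zip(implanted, per_pair):
                    try:
                        est = rigid_register(ref_c, flo_c, bins=bins,
                                             maxiter=rigid_maxiter)
                        total += offset(kt, est, weights)
                    except RegistrationError as exc:
                        logger.warning("lambda %g pair %d failed: %s",
                                       lam, p_i, exc)
                        total += math.inf
                    count += 1
            scores[lam] = total / count
            decomp_cache[lam] = (refs_c, flos_c)
        if not scores:
            raise ValueError(f"level {level}: no valid candidate below "
                             f"previous lambda {chosen[-1]:g}")
        best = min(scores.values())
        pick = max(lam for lam, s in scores.items() if s == best)
        chosen.append(pick)
        all_scores.append(scores)
        ref_chain, flo_chain = decomp_cache[pick]
    return LambdaEstimationResult(LambdaSchedule(tuple(chosen)),
                                  tuple(all_scores))


class LambdaCache:
    """Keyed store of estimated schedules with lookup-before-optimize.

    A schedule estimated once is reused for all incoming datasets of the
    same (modality, anatomy, size class); the size class is a coarse
    discretization of patient size chosen by the caller.
    """

    def __init__(self, path: str | os.PathLike | None = None):
        self.path = str(path) if path is not None else None
        self._store: dict[str, tuple[float, ...]] = {}
        if self.path and os.path.exists(self.path):
            with open(self.path) as fh:
                self._store = {k: tuple(v) for k, v in json.load(fh).items()}

    @staticmethod
    def key(modality: str, anatomy: str, size_class: str) -> str:
        return f"{modality.lower()}|{anatomy.lower()}|{size_class.lower()}"

    def lookup(self, modality: str, anatomy: str,
               size_class: str) -> LambdaSchedule | None:
        vals = self._store.get(self.key(modality, anatomy, size_class))
        return LambdaSchedule(vals) if vals is not None else None

    def store(self, modality: str, anatomy: str, size_class: str,
              schedule: LambdaSchedule) -> None:
        self._store[self.key(modality, anatomy, size_class)] = \
            tuple(schedule.values)
        if self.path:
            with open(self.path, "w") as fh:
                json.dump({k: list(v) for k, v in self._store.items()}, fh,
                          indent=2)

    def get_or_estimate(self, modality: str, anatomy: str, size_class: str,
                        estimator: Callable[[], LambdaSchedule | LambdaEstimationResult]
                        ) -> LambdaSchedule:
        cached = self.lookup(modality, anatomy, size_class)
        if cached is not None:
            return cached
        result = estimator()
        schedule = result.schedule if isinstance(result,
                                                 LambdaEstimationResult) \
            else result
        self.store(modality, anatomy, size_class, schedule)
        return schedule
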