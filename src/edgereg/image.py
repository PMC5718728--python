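"""Image and field containers, geometry conventions, warping and file I/O.

Conventions used throughout the package:

* arrays are indexed ``(x, y)`` in 2D and ``(x, y, z)`` in 3D, matching the
  on-disk world-axis semantics of NIfTI/MetaImage (readers transpose from the
  ``(z, y, x)`` layout SimpleITK exposes);
* voxel indices are 0-based; world coordinates are in millimetres with
  ``world = origin + index * spacing`` (axis-aligned frames only);
* displacement fields are stored in millimetres and map a fixed-space point
  ``p`` to the moving-space point ``p + v(p)`` (pull-back warping).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import ImageIOError, LatticeMismatchError, UnsupportedFormatError

__all__ = [
    "ScalarImage",
    "DisplacementField",
    "StructureMask",
    "read_image",
    "write_image",
    "read_field",
    "write_field",
    "read_mask",
    "write_mask",
    "warp_image",
    "subsample",
    "same_lattice",
]

_SUPPORTED_EXT = (".nii", ".nii.gz", ".mhd", ".mha")


def _as_tuple(value, ndim: int, name: str) -> tuple[float, ...]:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(ndim, float(arr[0]))
    if arr.size != ndim:
        raise ValueError(f"{name} must have {ndim} components, got {arr.size}")
    return tuple(float(v) for v in arr)


@dataclass(frozen=True)
class ScalarImage:
    """A scalar voxel lattice with world geometry.

    Parameters
    ----------
    data:
        2D or 3D array of intensities (CT numbers or normalized units).
    spacing:
        Voxel size in mm per axis (all positive).
    origin:
        World position (mm) of voxel index ``(0, ..., 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, ...] = None
    origin: tuple[float, ...] = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim not in (2, 3):
            raise ValueError(f"image must be 2D or 3D, got ndim={data.ndim}")
        if not np.all(np.isfinite(data)):
            raise ValueError("image data must be finite")
        spacing = _as_tuple(self.spacing if self.spacing is not None else 1.0,
                            data.ndim, "spacing")
        if any(s <= 0 for s in spacing):
            raise ValueError("all spacings must be > 0")
        origin = _as_tuple(self.origin if self.origin is not None else 0.0,
                           data.ndim, "origin")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel measure in mm^ndim (area in 2D, volume in 3D)."""
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[float, ...]:
        """Physical extent (mm) from first to last voxel centre per axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def with_data(self, data: np.ndarray) -> "ScalarImage":
        """A new image on the same lattice carrying ``data``."""
        return replace(self, data=np.asarray(data, dtype=float))

    def voxel_to_world(self, index) -> np.ndarray:
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def world_to_voxel(self, point) -> np.ndarray:
        point = np.asarray(point, dtype=float)
        return (point - np.asarray(self.origin)) / np.asarray(self.spacing)

    def world_axes(self) -> list[np.ndarray]:
        """Per-axis world coordinates of the voxel centres."""
        return [self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
                for a in range(self.ndim)]


@dataclass(frozen=True)
class DisplacementField:
    """Dense displacement vectors (mm) on a reference lattice.

    ``vectors[..., a]`` is the mm displacement along world axis ``a`` at each
    voxel; the field maps fixed-space ``p`` to moving-space ``p + v(p)``.
    """

    vectors: np.ndarray
    spacing: tuple[float, ...] = None
    origin: tuple[float, ...] = None

    def __post_init__(self):
        vec = np.asarray(self.vectors, dtype=float)
        if vec.ndim not in (3, 4) or vec.shape[-1] != vec.ndim - 1:
            raise ValueError(
                "vectors must have shape (*spatial, d) with d matching the "
                f"spatial dimensionality; got {vec.shape}")
        if not np.all(np.isfinite(vec)):
            raise ValueError("displacement components must be finite")
        ndim = vec.ndim - 1
        spacing = _as_tuple(self.spacing if self.spacing is not None else 1.0,
                            ndim, "spacing")
        if any(s <= 0 for s in spacing):
            raise ValueError("all spacings must be > 0")
        origin = _as_tuple(self.origin if self.origin is not None else 0.0,
                           ndim, "origin")
        object.__setattr__(self, "vectors", vec)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return self.vectors.ndim - 1

    @property
    def shape(self) -> tuple[int, ...]:
        return self.vectors.shape[:-1]

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean magnitude in mm."""
        return np.sqrt(np.sum(self.vectors ** 2, axis=-1))

    @classmethod
    def zeros_like(cls, image: ScalarImage) -> "DisplacementField":
        return cls(np.zeros(image.shape + (image.ndim,)),
                   image.spacing, image.origin)


@dataclass(frozen=True)
class StructureMask:
    """Binary voxel mask of an anatomical structure on an image lattice."""

    data: np.ndarray
    spacing: tuple[float, ...] = None
    origin: tuple[float, ...] = None
    label: str = "structure"

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim not in (2, 3):
            raise ValueError("mask must be 2D or 3D")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        data = data.astype(np.uint8)
        spacing = _as_tuple(self.spacing if self.spacing is not None else 1.0,
                            data.ndim, "spacing")
        origin = _as_tuple(self.origin if self.origin is not None else 0.0,
                           data.ndim, "origin")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def volume_mm(self) -> float:
        return float(self.data.sum() * np.prod(self.spacing))

    def with_data(self, data, label=None) -> "StructureMask":
        return StructureMask(data, self.spacing, self.origin,
                             label if label is not None else self.label)


def same_lattice(a, b, atol: float = 1e-6) -> bool:
    """Whether two containers share shape, spacing and origin."""
    return (a.shape == b.shape
            and np.allclose(a.spacing, b.spacing, atol=atol)
            and np.allclose(a.origin, b.origin, atol=atol))


def _require_same_lattice(a, b, what: str = "inputs"):
    if not same_lattice(a, b):
        raise LatticeMismatchError(
            f"{what} must share the same lattice: "
            f"{a.shape}/{a.spacing}/{a.origin} vs {b.shape}/{b.spacing}/{b.origin}")


# ---------------------------------------------------------------------------
# File I/O (NIfTI-1 and MetaImage via SimpleITK)
# ---------------------------------------------------------------------------

def _check_ext(path: str):
    p = str(path).lower()
    if not any(p.endswith(e) for e in _SUPPORTED_EXT):
        raise UnsupportedFormatError(
            f"unsupported extension for {path!r}; expected one of {_SUPPORTED_EXT}")


def _check_direction(img: sitk.Image, path):
    d = np.asarray(img.GetDirection()).reshape(img.GetDimension(), -1)
    if not np.allclose(d, np.eye(img.GetDimension()), atol=1e-6):
        raise ImageIOError(
            f"{path!r} has a non-identity direction matrix; only axis-aligned "
            "frames are supported")


def _read_sitk(path) -> sitk.Image:
    _check_ext(path)
    if not os.path.exists(path):
        raise ImageIOError(f"no such file: {path!r}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # malformed header, truncated file, ...
        raise ImageIOError(f"failed to read {path!r}: {exc}") from exc
    _check_direction(img, path)
    return img


def read_image(path) -> ScalarImage:
    """Read a scalar NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha) file."""
    img = _read_sitk(path)
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ImageIOError(f"{path!r} is vector-valued; use read_field")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return ScalarImage(arr.T.astype(float), img.GetSpacing(), img.GetOrigin())


def write_image(image: ScalarImage, path) -> None:
    """Write a scalar image; round-trips data, spacing and origin bit-exactly."""
    _check_ext(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(image.data.T))
    img.SetSpacing(image.spacing)
    img.SetOrigin(image.origin)
    sitk.WriteImage(img, str(path))


def read_field(path) -> DisplacementField:
    """Read a vector-valued image as a displacement field (mm components)."""
    img = _read_sitk(path)
    d = img.GetDimension()
    if img.GetNumberOfComponentsPerPixel() != d:
        raise ImageIOError(
            f"{path!r}: expected {d} vector components, "
            f"got {img.GetNumberOfComponentsPerPixel()}")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, d)
    axes = tuple(range(d - 1, -1, -1)) + (d,)
    return DisplacementField(np.transpose(arr, axes).astype(float),
                             img.GetSpacing(), img.GetOrigin())


def write_field(fld: DisplacementField, path) -> None:
    _check_ext(path)
    d = fld.ndim
    axes = tuple(range(d - 1, -1, -1)) + (d,)
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(fld.vectors, axes)), isVector=True)
    img.SetSpacing(fld.spacing)
    img.SetOrigin(fld.origin)
    sitk.WriteImage(img, str(path))


def read_mask(path, label: str = "structure") -> StructureMask:
    img = read_image(path)
    return StructureMask((img.data > 0.5).astype(np.uint8),
                         img.spacing, img.origin, label)


def write_mask(mask: StructureMask, path) -> None:
    _check_ext(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(mask.data.T))
    img.SetSpacing(mask.spacing)
    img.SetOrigin(mask.origin)
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Sampling and warping
# ---------------------------------------------------------------------------

def _moving_coords(moving: ScalarImage, field: DisplacementField) -> np.ndarray:
    """Moving-image voxel coordinates sampled at each fixed-lattice point."""
    axes = np.meshgrid(*[fo + fs * np.arange(n)
                         for fo, fs, n in zip(field.origin, field.spacing,
                                              field.shape)],
                       indexing="ij")
    coords = np.stack(axes, axis=-1) + field.vectors  # world mm target points
    coords = (coords - np.asarray(moving.origin)) / np.asarray(moving.spacing)
    return np.moveaxis(coords, -1, 0)


def sample_at_voxel_coords(moving: ScalarImage, coords: np.ndarray,
                           interp: str = "linear", pad: float = 0.0) -> np.ndarray:
    """Sample ``moving`` at fractional voxel coordinates ``coords`` (d, ...)."""
    if interp not in ("linear", "nearest"):
        raise ValueError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    order = 1 if interp == "linear" else 0
    return ndimage.map_coordinates(moving.data, coords, order=order,
                                   mode="constant", cval=pad)


def warp_image(moving: ScalarImage, fld: DisplacementField,
               interp: str = "linear", pad: float = 0.0) -> ScalarImage:
    """Pull-back warp: output(p) = moving(p + v(p)) on the field's lattice.

    Out-of-bounds samples take the padding value (default 0).
    """
    if moving.ndim != fld.ndim:
        raise LatticeMismatchError(
            f"moving image is {moving.ndim}D but field is {fld.ndim}D")
    coords = _moving_coords(moving, fld)
    data = sample_at_voxel_coords(moving, coords, interp=interp, pad=pad)
    return ScalarImage(data, fld.spacing, fld.origin)


def warp_validity(moving: ScalarImage, fld: DisplacementField) -> np.ndarray:
    """Boolean mask of fixed-lattice voxels whose warp target lies inside
    the moving image (no padding involved)."""
    coords = _moving_coords(moving, fld)
    valid = np.ones(fld.shape, dtype=bool)
    for a in range(moving.ndim):
        valid &= (coords[a] >= 0) & (coords[a] <= moving.shape[a] - 1)
    return valid


def subsample(image: ScalarImage, factor) -> ScalarImage:
    """Keep every ``factor``-th voxel after anti-alias Gaussian smoothing.

    Spacing is multiplied by the factor; the origin stays at the first kept
    voxel.  ``factor`` may be a scalar or one integer per axis, each >= 1.
    """
    factors = np.atleast_1d(np.asarray(factor, dtype=int))
    if factors.size == 1:
        factors = np.full(image.ndim, int(factors[0]))
    if factors.size != image.ndim:
        raise ValueError("need one subsampling factor per axis")
    if np.any(factors < 1):
        raise ValueError("subsampling factors must be >= 1")
    if np.any(factors > np.asarray(image.shape)):
        raise ValueError("subsampling factor larger than axis extent")
    if np.all(factors == 1):
        return image
    sigmas = [f / 2.0 if f > 1 else 0.0 for f in factors]
    smoothed = ndimage.gaussian_filter(image.data, sigmas, mode="nearest")
    sl = tuple(slice(None, None, int(f)) for f in factors)
    return ScalarImage(smoothed[sl],
                       tuple(s * f for s, f in zip(image.spacing, factors)),
                       image.origin)
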