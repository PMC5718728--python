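"""Joint-histogram estimation and normalized mutual information (NMI).

NMI(A; B) = (H(A) + H(B)) / H(A, B) with Shannon entropies of the discrete
joint intensity histogram; it lies in [1, 2] (1 for independent images, 2
when one image determines the other) and, unlike plain mutual information,
is robust to changes in the size of the image overlap — the property that
matters when a deformation moves tissue in and out of the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LatticeMismatchError
from .image import ScalarImage, StructureMask, same_lattice

__all__ = ["JointHistogram", "joint_histogram", "nmi", "nmi_images",
           "entropy_bits", "robust_range", "bin_indices"]

DEFAULT_BINS = 32
# robust intensity range: clips CT reconstruction outliers without
# deadening the histogram at subsampled resolutions
ROBUST_PERCENTILES = (0.5, 99.5)


@dataclass(frozen=True)
class JointHistogram:
    """B x B joint bin counts plus the bin edges used for each image."""

    counts: np.ndarray
    a_edges: np.ndarray
    b_edges: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def a_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def b_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def robust_range(data: np.ndarray,
                 percentiles=ROBUST_PERCENTILES) -> tuple[float, float]:
    lo, hi = np.percentile(data, percentiles)
    if hi <= lo:
        hi = lo + 1.0
    return float(lo), float(hi)


def bin_indices(values: np.ndarray, lo: float, hi: float,
                bins: int) -> np.ndarray:
    """Linear binning with out-of-range values clipped into the end bins."""
    idx = np.floor((values - lo) / (hi - lo) * bins).astype(np.intp)
    return np.clip(idx, 0, bins - 1)


def joint_histogram(a: ScalarImage, b: ScalarImage, bins: int = DEFAULT_BINS,
                    mask: StructureMask | np.ndarray | None = None,
                    a_range=None, b_range=None) -> JointHistogram:
    """Joint intensity histogram of two images on the same lattice.

    ``mask`` (binary, same lattice) restricts the samples, e.g. to the valid
    overlap of a warped image.  Bin edges default to each image's robust
    intensity range.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if not same_lattice(a, b):
        raise LatticeMismatchError("histogram inputs must share a lattice")
    av, bv = a.data, b.data
    if mask is not None:
        m = mask.data if isinstance(mask, StructureMask) else np.asarray(mask)
        if m.shape != a.shape:
            raise LatticeMismatchError("mask shape differs from images")
        sel = m.astype(bool)
        av, bv = av[sel], bv[sel]
    av, bv = av.ravel(), bv.ravel()
    alo, ahi = robust_range(av) if a_range is None else map(float, a_range)
    blo, bhi = robust_range(bv) if b_range is None else map(float, b_range)
    ai = bin_indices(av, alo, ahi, bins)
    bi = bin_indices(bv, blo, bhi, bins)
    counts = np.bincount(ai * bins + bi, minlength=bins * bins)
    return JointHistogram(counts.reshape(bins, bins).astype(np.int64),
                          np.linspace(alo, ahi, bins + 1),
                          np.linspace(blo, bhi, bins + 1))


def entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a (possibly unnormalized) histogram,
    with 0*log(0) := 0."""
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def nmi(h: JointHistogram | np.ndarray) -> float:
    """Studholme's normalized mutual information (H(A)+H(B))/H(A,B)."""
    counts = h.counts if isinstance(h, JointHistogram) else np.asarray(h)
    if counts.sum() <= 0:
        raise ValueError("empty overlap: no samples in the joint histogram")
    ha = entropy_bits(counts.sum(axis=1))
    hb = entropy_bits(counts.sum(axis=0))
    hab = entropy_bits(counts.ravel())
    if hab == 0.0:  # both images constant over the overlap
        return 2.0
    return (ha + hb) / hab


def nmi_images(a: ScalarImage, b: ScalarImage, bins: int = DEFAULT_BINS,
               mask=None, a_range=None, b_range=None) -> float:
    return nmi(joint_histogram(a, b, bins=bins, mask=mask,
                               a_range=a_range, b_range=b_range))
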