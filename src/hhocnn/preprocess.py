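"""Impulse denoising and mean-split sub-histogram contrast enhancement.

Two classical operations prepare an MR slice for segmentation:

* a sliding-window **median filter** removes salt-and-pepper impulses while
  preserving edges — each output pixel is the median of its window, so the
  output value is always a member of the input window multiset;

* **sub-histogram equalization** splits the intensity histogram at
  recursively computed weighted-mean points and equalizes each segment
  independently onto its own input interval.  Equalizing per segment, in the
  style of brightness-preserving bi-histogram equalization, limits the
  global brightness shift of plain histogram equalization while still
  stretching local contrast.

The split point of an interval ``(a, b]`` is the CDF-weighted mean gray
level

    X = sum_l l * CDF(l) / sum_l CDF(l),   l in the occupied levels of (a, b]

and the recursion halves intervals until ``t`` segments exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import GRAY_LEVELS, validate_gray_image

__all__ = [
    "HistogramModel",
    "median_filter",
    "compute_histogram",
    "split_points",
    "equalize",
]


def median_filter(
    img: np.ndarray, window: int = 3, threshold: float | None = None
) -> np.ndarray:
    """Median-filter *img* with a ``window x window`` sliding window.

    Borders are handled by edge replication.  With ``threshold`` set, a pixel
    is replaced by its window median only when it deviates from that median
    by more than the threshold (impulse-detection mode); by default every
    pixel is replaced unconditionally.
    """
    img = validate_gray_image(img)
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window side must be odd and >= 3, got {window}")
    med = ndimage.median_filter(img, size=window, mode="nearest")
    if threshold is None:
        return med
    keep = np.abs(img.astype(np.int64) - med.astype(np.int64)) <= threshold
    return np.where(keep, img, med).astype(img.dtype)


@dataclass
class HistogramModel:
    """Gray-level histogram with its PDF and CDF."""

    counts: np.ndarray  # occurrences per gray level, length `levels`
    levels: int = GRAY_LEVELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.levels,):
            raise ValueError("counts must have one entry per gray level")
        if self.n == 0:
            raise ValueError("empty histogram")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def pdf(self) -> np.ndarray:
        return self.counts / self.n

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pdf)


def compute_histogram(img: np.ndarray, levels: int = GRAY_LEVELS) -> HistogramModel:
    """Count occurrences of every gray level of *img*."""
    img = validate_gray_image(img, levels)
    counts = np.bincount(img.ravel(), minlength=levels)
    return HistogramModel(counts=counts, levels=levels)


def _weighted_mean_split(hist: HistogramModel, a: int, b: int) -> int:
    """CDF-weighted mean gray level over the occupied levels in ``(a, b]``."""
    cdf = hist.cdf
    lo = a + 1 if a > 0 else 0  # the first interval starts at level 0
    levels = np.arange(lo, b + 1)
    occupied = hist.counts[lo : b + 1] > 0
    levels = levels[occupied]
    weights = cdf[levels]
    x = float(np.sum(levels * weights) / np.sum(weights))
    return int(np.floor(x))


def split_points(hist: HistogramModel, t: int) -> list[int]:
    """Recursive weighted-mean splitting of the histogram into *t* segments.

    Returns the ``t - 1`` interior split points, strictly increasing.  A
    split point ``x`` divides ``[a, b]`` into ``[a, x]`` and ``[x + 1, b]``;
    the recursion assigns ``ceil(t/2)`` segments to the left part and
    ``floor(t/2)`` to the right.  Raises if an interval does not hold enough
    occupied gray levels to host its share of segments.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    occupied_total = int(np.count_nonzero(hist.counts))
    if t > occupied_total:
        raise ValueError(
            f"cannot split {occupied_total} occupied level(s) into {t} segments"
        )

    def recurse(a: int, b: int, k: int) -> list[int]:
        if k == 1:
            return []
        occ = np.flatnonzero(hist.counts[a : b + 1]) + a
        if len(occ) < k:
            raise ValueError(
                f"interval [{a}, {b}] holds {len(occ)} occupied level(s), "
                f"cannot split into {k}"
            )
        x = _weighted_mean_split(hist, a, b)
        # both halves must contain at least one occupied level:
        # occ[0] <= x < occ[-1]
        x = min(max(x, int(occ[0])), int(occ[-1]) - 1)
        k_left = (k + 1) // 2
        return recurse(a, x, k_left) + [x] + recurse(x + 1, b, k - k_left)

    return recurse(0, hist.levels - 1, t)


def _equalize_interval(
    img: np.ndarray, hist: HistogramModel, a: int, b: int
) -> np.ndarray:
    """Histogram-equalize the pixels of *img* lying in ``[a, b]`` onto ``[a, b]``.

    Classical CDF mapping with min-CDF normalization, restricted to the
    sub-image: a single occupied level maps to itself.
    """
    sel = (img >= a) & (img <= b)
    out = np.zeros_like(img)
    counts = hist.counts[a : b + 1].astype(np.float64)
    n_k = counts.sum()
    if n_k == 0:
        return out
    cdf_k = np.cumsum(counts) / n_k
    occ = np.flatnonzero(counts)
    cdf_min = cdf_k[occ[0]]
    if cdf_min >= 1.0:  # single occupied level: identity
        mapping = np.arange(a, b + 1)
    else:
        mapping = a + np.rint((cdf_k - cdf_min) / (1.0 - cdf_min) * (b - a))
    mapping = np.clip(mapping, a, b).astype(img.dtype)
    out[sel] = mapping[img[sel] - a]
    return out


def equalize(img: np.ndarray, t: int = 2) -> np.ndarray:
    """Sub-histogram equalization with *t* mean-split segments.

    Each segment of the gray-level axis is equalized independently onto its
    own input interval, so segment ordering (and hence the coarse intensity
    ordering of the image) is preserved and the output stays in
    ``[0, levels - 1]``.
    """
    img = validate_gray_image(img)
    hist = compute_histogram(img)
    splits = split_points(hist, t)
    edges = [0] + [s + 1 for s in splits] + [hist.levels]
    out = np.zeros_like(img)
    for a, b_next in zip(edges[:-1], edges[1:]):
        out += _equalize_interval(img, hist, a, b_next - 1)
    return out
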