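"""Statistical and texture descriptors of a segmented region.

Two families of features are extracted from the candidate region (falling
back to the whole image when segmentation yields nothing usable):

* first-order statistics of the intensity multiset — mean, standard
  deviation, the central moments ``m2..m4``, moment skewness
  ``m3 / m2^1.5`` and kurtosis ``m4 / m2^2`` (population moments; constant
  input is assigned skewness and kurtosis 0 so degenerate regions do not
  produce NaNs);

* gray-level co-occurrence (GLCM) texture statistics — contrast,
  correlation, energy and homogeneity of the symmetrized, normalized
  co-occurrence matrix accumulated over a set of pixel offsets restricted
  to in-region pairs:

      contrast    = sum_ij P_ij (i - j)^2
      correlation = sum_ij P_ij (i - mu_i)(j - mu_j) / (sigma_i sigma_j)
      energy      = sum_ij P_ij^2
      homogeneity = sum_ij P_ij / (1 + (i - j)^2)

  with correlation defined as 1 when either marginal variance vanishes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .phantom import GRAY_LEVELS, LabeledDataset, validate_gray_image

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureVector",
    "DEFAULT_OFFSETS",
    "statistical_features",
    "glcm_features",
    "extract_features",
    "build_feature_table",
    "FEATURE_COLUMNS",
]

#: Default co-occurrence offsets: E, S, SE, NE at distance 1.
DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))

#: Number of quantization bins for the co-occurrence matrix.
DEFAULT_GLCM_LEVELS = 16


@dataclass
class FeatureVector:
    mean: float = 0.0
    std: float = 0.0
    skewness: float = 0.0
    kurtosis: float = 0.0
    moment2: float = 0.0
    moment3: float = 0.0
    moment4: float = 0.0
    area: int = 0
    glcm_contrast: float = 0.0
    glcm_correlation: float = 0.0
    glcm_energy: float = 0.0
    glcm_homogeneity: float = 0.0


FEATURE_COLUMNS = list(asdict(FeatureVector()).keys())


def statistical_features(pixels: np.ndarray, fisher: bool = False) -> FeatureVector:
    """First-order (moment) statistics of an intensity multiset.

    With ``fisher=True`` the kurtosis is reported as excess kurtosis
    (``m4/m2^2 - 3``).
    """
    x = np.asarray(pixels, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty pixel set")
    mean = float(x.mean())
    d = x - mean
    m2 = float(np.mean(d**2))
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    if m2 > 0:
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
        if fisher:
            kurt -= 3.0
    else:
        skew = 0.0
        kurt = 0.0
    return FeatureVector(
        mean=mean,
        std=float(np.sqrt(m2)),
        skewness=skew,
        kurtosis=kurt,
        moment2=m2,
        moment3=m3,
        moment4=m4,
        area=int(x.size),
    )


def glcm_matrix(
    img: np.ndarray,
    mask: np.ndarray | None = None,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    levels: int = DEFAULT_GLCM_LEVELS,
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix over in-region pixel pairs.

    Intensities are quantized to *levels* equal-width bins of ``[0, 255]``.
    A pair ``(p, p + offset)`` contributes when both pixels lie inside the
    mask; the matrix is symmetrized (both pair orders counted) and
    normalized to sum to 1.
    """
    img = validate_gray_image(img)
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("mask shape differs from image shape")
    q = (img.astype(np.int64) * levels) // GRAY_LEVELS
    h, w = img.shape
    counts = np.zeros((levels, levels), dtype=np.float64)
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        src_m = mask[r0:r1, c0:c1]
        dst_m = mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = src_m & dst_m
        i = q[r0:r1, c0:c1][valid]
        j = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc][valid]
        np.add.at(counts, (i, j), 1.0)
        np.add.at(counts, (j, i), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("region admits no valid pixel pair for the given offsets")
    return counts / total


def glcm_features(
    img: np.ndarray,
    mask: np.ndarray | None = None,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    levels: int = DEFAULT_GLCM_LEVELS,
) -> dict[str, float]:
    """Contrast, correlation, energy and homogeneity of the region's GLCM."""
    p = glcm_matrix(img, mask, offsets, levels)
    idx = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    contrast = float((p * (ii - jj) ** 2).sum())
    mu_i = float((p.sum(axis=1) * idx).sum())
    mu_j = float((p.sum(axis=0) * idx).sum())
    var_i = float((p.sum(axis=1) * (idx - mu_i) ** 2).sum())
    var_j = float((p.sum(axis=0) * (idx - mu_j) ** 2).sum())
    if var_i > 0 and var_j > 0:
        corr = float((p * (ii - mu_i) * (jj - mu_j)).sum() / np.sqrt(var_i * var_j))
    else:
        corr = 1.0
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    return {
        "glcm_contrast": contrast,
        "glcm_correlation": corr,
        "glcm_energy": energy,
        "glcm_homogeneity": homogeneity,
    }


def extract_features(
    img: np.ndarray,
    mask: np.ndarray | None = None,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    levels: int = DEFAULT_GLCM_LEVELS,
) -> FeatureVector:
    """Full feature vector (statistics + texture) of a region of *img*."""
    img = validate_gray_image(img)
    if mask is not None and not mask.any():
        mask = None
    pixels = img[mask] if mask is not None else img.ravel()
    fv = statistical_features(pixels)
    try:
        tex = glcm_features(img, mask, offsets, levels)
    except ValueError:
        logger.warning("no valid co-occurrence pairs; texture features zeroed")
        tex = {
            "glcm_contrast": 0.0,
            "glcm_correlation": 0.0,
            "glcm_energy": 0.0,
            "glcm_homogeneity": 0.0,
        }
    for k, v in tex.items():
        setattr(fv, k, v)
    return fv


def build_feature_table(
    dataset: LabeledDataset,
    masks: list[np.ndarray | None] | None = None,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    levels: int = DEFAULT_GLCM_LEVELS,
) -> pd.DataFrame:
    """One feature row per image, final column ``label``.

    *masks* holds the candidate-region mask per image; a missing or empty
    mask falls back to whole-image features (logged).
    """
    rows = []
    for i, img in enumerate(dataset.images):
        mask = masks[i] if masks is not None else None
        if mask is None or not np.asarray(mask).any():
            if masks is not None:
                logger.warning("image %d has no candidate region; using whole image", i)
            mask = None
        fv = extract_features(img, mask, offsets, levels)
        row = asdict(fv)
        row["label"] = int(dataset.labels[i])
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["label"])
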