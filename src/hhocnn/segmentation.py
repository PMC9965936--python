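"""Tumor-region segmentation: fuzzy c-means, seeded region growing, scoring.

The segmentation stage clusters pixel intensities with fuzzy c-means (FCM),
turns each cluster into a spatial seed (the pixel with maximal membership to
the cluster), grows a region from every seed by breadth-first admission of
connected neighbors whose intensity is within a threshold of the region's
running mean, and finally ranks the grown regions by a compactness score
(circularity times boundary edge support) to pick the candidate tumor.

FCM alternates the two coupled updates

    V_j   = sum_i mu_ij^m x_i / sum_i mu_ij^m            (centers)
    mu_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1))            (memberships)

where ``m > 1`` is the fuzziness index; the objective
``sum_ij mu_ij^m d_ij^2`` is nonincreasing under this alternation.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .phantom import validate_gray_image

logger = logging.getLogger(__name__)

__all__ = [
    "FuzzyPartition",
    "RegionMap",
    "CandidateRegion",
    "fcm_fit",
    "select_seeds",
    "region_grow",
    "select_candidate",
    "segmentation_metrics",
]


@dataclass
class FuzzyPartition:
    """Converged (or budget-exhausted) fuzzy c-means partition."""

    centers: np.ndarray  # (c, d)
    memberships: np.ndarray  # (n, c), rows sum to 1
    objective_history: np.ndarray
    n_iter: int
    converged: bool

    @property
    def c(self) -> int:
        return self.centers.shape[0]

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


def _fcm_memberships(x: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    # d2: squared Euclidean distances (n, c)
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
    mu = np.empty_like(d2)
    ok = ~any_zero
    mu[ok] = inv[ok] / inv[ok].sum(axis=1, keepdims=True)
    # a point sitting exactly on a center belongs to it entirely
    if any_zero.any():
        mu[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    return mu


def fcm_fit(
    points: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 300,
    seed: int = 0,
) -> FuzzyPartition:
    """Fit fuzzy c-means to *points* (``(n,)`` or ``(n, d)`` array).

    Memberships are initialized uniformly at random (rows normalized to 1)
    from *seed*; the alternation stops when the maximum center displacement
    drops below *tol* or after *max_iter* iterations.
    """
    x = np.asarray(points, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if not np.isfinite(x).all():
        raise ValueError("non-finite data")
    if c < 1 or c > n:
        raise ValueError(f"need 1 <= c <= n, got c={c}, n={n}")
    if m <= 1:
        raise ValueError("fuzziness index m must be > 1")
    if tol <= 0:
        raise ValueError("tol must be positive")

    rng = np.random.default_rng(seed)
    mu = rng.uniform(size=(n, c))
    mu /= mu.sum(axis=1, keepdims=True)

    centers = np.zeros((c, x.shape[1]))
    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu**m
        denom = w.sum(axis=0)[:, None]
        denom[denom == 0] = 1e-300
        new_centers = (w.T @ x) / denom
        mu = _fcm_memberships(x, new_centers, m)
        d2 = ((x[:, None, :] - new_centers[None, :, :]) ** 2).sum(axis=2)
        history.append(float((mu**m * d2).sum()))
        shift = np.abs(new_centers - centers).max() if it > 1 else np.inf
        centers = new_centers
        if shift < tol:
            converged = True
            break
    return FuzzyPartition(
        centers=centers,
        memberships=mu,
        objective_history=np.array(history),
        n_iter=it,
        converged=converged,
    )


def fcm_fit_image(img: np.ndarray, c: int = 3, **kwargs) -> FuzzyPartition:
    """FCM on the pixel intensities of *img* (row-major flattening)."""
    img = validate_gray_image(img)
    return fcm_fit(img.ravel().astype(np.float64), c, **kwargs)


def select_seeds(
    partition: FuzzyPartition, img: np.ndarray
) -> list[tuple[int, int, int]]:
    """One seed per nonempty cluster: the maximal-membership pixel.

    The printed cluster center is an intensity, not a location; mapping it
    to the pixel with highest membership gives region growing a spatial
    origin inside the cluster.  Ties break in row-major order (``argmax``).
    Returns ``(row, col, cluster)`` triples; clusters that own no pixel
    under the hard assignment are skipped with a warning.
    """
    img = validate_gray_image(img)
    h, w = img.shape
    if partition.memberships.shape[0] != h * w:
        raise ValueError("partition does not match image size")
    hard = partition.hard_labels()
    seeds = []
    for j in range(partition.c):
        if not (hard == j).any():
            logger.warning("cluster %d owns no pixel; skipped", j)
            continue
        flat = int(np.argmax(partition.memberships[:, j]))
        seeds.append((flat // w, flat % w, j))
    return seeds


_OFFSETS = {
    4: ((-1, 0), (1, 0), (0, -1), (0, 1)),
    8: ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)),
}


@dataclass
class RegionMap:
    """Pixel labels from seeded region growing (0 = unassigned)."""

    labels: np.ndarray  # int, 0 background, k >= 1 region k
    seeds: list[tuple[int, int]]
    tau: float
    connectivity: int
    region_means: dict[int, float] = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    def region_mask(self, k: int) -> np.ndarray:
        return self.labels == k


def region_grow(
    img: np.ndarray,
    seeds: list[tuple[int, int]],
    tau: float,
    connectivity: int = 4,
    reference: str = "mean",
) -> RegionMap:
    """Grow one region per seed by breadth-first neighbor admission.

    All seeds are enqueued together so regions expand simultaneously; a
    pixel is claimed by the first region whose front reaches it, and is
    admitted when ``|intensity - region reference| <= tau``.  The reference
    is the running mean of the region's admitted intensities (default) or
    the fixed seed intensity (``reference="seed"``).  Growth stops when no
    front can advance (the zero-change termination criterion), leaving the
    regions pairwise disjoint and connected.
    """
    img = validate_gray_image(img)
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if connectivity not in _OFFSETS:
        raise ValueError("connectivity must be 4 or 8")
    if not seeds:
        raise ValueError("need at least one seed")
    h, w = img.shape
    labels = np.zeros((h, w), dtype=np.int32)
    sums = {}
    counts = {}
    queue: deque[tuple[int, int]] = deque()
    for k, (r, c) in enumerate(seeds, start=1):
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"seed {(r, c)} out of bounds for {h}x{w} image")
        if labels[r, c] == 0:
            labels[r, c] = k
            sums[k] = float(img[r, c])
            counts[k] = 1
            queue.append((r, c))
    offsets = _OFFSETS[connectivity]
    img_f = img.astype(np.float64)
    while queue:
        r, c = queue.popleft()
        k = labels[r, c]
        if reference == "mean":
            ref = sums[k] / counts[k]
        else:
            ref = float(img_f[seeds[k - 1]])
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] == 0:
                if abs(img_f[rr, cc] - ref) <= tau:
                    labels[rr, cc] = k
                    sums[k] += img_f[rr, cc]
                    counts[k] += 1
                    queue.append((rr, cc))
    means = {k: sums[k] / counts[k] for k in sums}
    return RegionMap(
        labels=labels,
        seeds=[(r, c) for r, c in seeds],
        tau=tau,
        connectivity=connectivity,
        region_means=means,
    )


@dataclass
class CandidateRegion:
    """A grown region ranked as the putative tumor."""

    region_id: int
    mask: np.ndarray
    boundary: np.ndarray
    circularity: float
    edge_support: float
    score: float
    rank: int = 0

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def _boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Pixels of *mask* with a 4-neighbor outside the mask (or on the edge)."""
    inner = np.ones_like(mask)
    inner[1:, :] &= mask[:-1, :]
    inner[:-1, :] &= mask[1:, :]
    inner[:, 1:] &= mask[:, :-1]
    inner[:, :-1] &= mask[:, 1:]
    inner[0, :] = inner[-1, :] = False
    inner[:, 0] = inner[:, -1] = False
    return mask & ~inner


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(img.astype(np.float64))
    return np.hypot(gy, gx)


def select_candidate(regions: RegionMap, img: np.ndarray) -> CandidateRegion:
    """Rank grown regions and return the best candidate tumor region.

    Score = circularity x edge support, where circularity is
    ``4 * pi * area / perimeter^2`` (perimeter = boundary pixel count) and
    edge support is the fraction of boundary pixels whose gradient magnitude
    exceeds the image's median gradient — a proxy for a compact, strongly
    edged ("circle-like") region.  Ties break toward the larger area.
    """
    img = validate_gray_image(img)
    n = regions.n_regions
    if n < 1:
        raise ValueError("no regions to select from")
    grad = _gradient_magnitude(img)
    med_grad = float(np.median(grad))
    scored = []
    for k in range(1, n + 1):
        mask = regions.region_mask(k)
        area = int(mask.sum())
        if area == 0:
            continue
        boundary = _boundary_mask(mask)
        perim = max(int(boundary.sum()), 1)
        circ = 4.0 * np.pi * area / perim**2
        edge = float((grad[boundary] > med_grad).mean()) if boundary.any() else 0.0
        scored.append(
            CandidateRegion(
                region_id=k,
                mask=mask,
                boundary=boundary,
                circularity=circ,
                edge_support=edge,
                score=circ * edge,
            )
        )
    if not scored:
        raise ValueError("no nonempty regions")
    scored.sort(key=lambda r: (r.score, r.area), reverse=True)
    for rank, reg in enumerate(scored, start=1):
        reg.rank = rank
    return scored[0]


def segmentation_metrics(
    predicted: np.ndarray, truth: np.ndarray
) -> tuple[float, float]:
    """Pixel accuracy and Dice overlap between two boolean masks.

    Dice of two empty masks is defined as 1 (perfect agreement on "nothing").
    """
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError("mask shapes differ")
    accuracy = float((predicted == truth).mean())
    denom = predicted.sum() + truth.sum()
    if denom == 0:
        return accuracy, 1.0
    dice = 2.0 * float(np.logical_and(predicted, truth).sum()) / float(denom)
    return accuracy, dice
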