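"""Fuzzy c-means, seed selection, region growing, candidate ranking."""

import numpy as np
import pytest
from scipy import ndimage

from hhocnn.phantom import PhantomSpec, generate_phantom
from hhocnn.segmentation import (
    fcm_fit,
    fcm_fit_image,
    region_grow,
    segmentation_metrics,
    select_candidate,
    select_seeds,
)


def reference_fcm_1d(x, centers, m, iters=200):
    """Independent fixed-point iteration of the center/membership updates."""
    x = np.asarray(x, dtype=float)
    centers = np.asarray(centers, dtype=float)
    for _ in range(iters):
        d2 = (x[:, None] - centers[None, :]) ** 2
        d2 = np.maximum(d2, 1e-12)
        mu = 1.0 / (d2 ** (1 / (m - 1)) * np.sum(d2 ** (-1 / (m - 1)), axis=1)[:, None])
        centers = (mu**m).T @ x / (mu**m).sum(axis=0)
    return centers, mu


class TestFcmFit:
    def test_single_cluster_closed_form(self, rng):
        x = rng.normal(50, 10, size=40)
        part = fcm_fit(x, c=1, seed=0)
        assert np.allclose(part.memberships, 1.0)
        assert np.isclose(part.centers[0, 0], x.mean())

    def test_two_cluster_toy_matches_reference(self):
        x = np.array([0.0, 0.0, 10.0, 10.0])
        part = fcm_fit(x, c=2, m=2.0, tol=1e-8, seed=7)
        got = np.sort(part.centers.ravel())
        ref_centers, _ = reference_fcm_1d(x, [1.0, 9.0], m=2.0)
        np.testing.assert_allclose(got, np.sort(ref_centers), atol=0.1)
        np.testing.assert_allclose(got, [0.0, 10.0], atol=0.1)
        # a 0-point belongs almost entirely to the near center
        near = int(np.argmin(part.centers.ravel()))
        assert part.memberships[0, near] > 0.99

    def test_point_on_center_gets_full_membership(self):
        x = np.array([0.0, 5.0, 10.0])
        part = fcm_fit(x, c=3, m=2.0, tol=1e-10, seed=1)
        # after convergence each point sits on a center
        for i in range(3):
            assert np.isclose(part.memberships[i].max(), 1.0, atol=1e-6)

    def test_membership_rows_sum_to_one(self, rng):
        x = rng.uniform(0, 255, size=200)
        part = fcm_fit(x, c=4, seed=3)
        np.testing.assert_allclose(part.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_nonincreasing(self, rng):
        x = rng.uniform(0, 255, size=300)
        part = fcm_fit(x, c=3, seed=5, tol=1e-10)
        diffs = np.diff(part.objective_history)
        assert (diffs <= 1e-8 * np.abs(part.objective_history[:-1]) + 1e-12).all()

    def test_errors(self):
        with pytest.raises(ValueError):
            fcm_fit(np.array([1.0, 2.0]), c=3)
        with pytest.raises(ValueError):
            fcm_fit(np.array([1.0, np.nan]), c=1)
        with pytest.raises(ValueError):
            fcm_fit(np.array([1.0, 2.0]), c=2, m=1.0)

    def test_matches_midpoint_threshold_on_two_intensity_phantom(self):
        img, _, _ = generate_phantom(PhantomSpec(tumor=False))
        part = fcm_fit_image(img, c=2, seed=0)
        bright = int(np.argmax(part.centers.ravel()))
        got = (part.hard_labels() == bright).reshape(img.shape)
        midpoint = (20 + 120) / 2.0
        np.testing.assert_array_equal(got, img > midpoint)


class TestSelectSeeds:
    def test_one_seed_per_blob(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        img[:, 4:] = 200
        part = fcm_fit_image(img, c=2, seed=0)
        seeds = select_seeds(part, img)
        cols = sorted(c for _, c, _ in seeds)
        assert len(seeds) == 2
        assert cols[0] < 4 <= cols[1]

    def test_constant_image_tie_breaks_row_major(self):
        img = np.full((5, 5), 100, dtype=np.uint8)
        part = fcm_fit_image(img, c=1, seed=0)
        seeds = select_seeds(part, img)
        assert seeds == [(0, 0, 0)]

    def test_brightest_cluster_seed_inside_tumor(self, clean_tumor_spec):
        img, mask, _ = generate_phantom(clean_tumor_spec)
        part = fcm_fit_image(img, c=3, seed=0)
        seeds = select_seeds(part, img)
        bright_cluster = int(np.argmax(part.centers.ravel()))
        (r, c) = next((r, c) for r, c, j in seeds if j == bright_cluster)
        assert mask[r, c]


class TestRegionGrow:
    def test_uniform_image_full_coverage(self):
        img = np.full((6, 6), 50, dtype=np.uint8)
        rmap = region_grow(img, [(0, 0)], tau=1.0)
        assert (rmap.labels == 1).all()

    def test_tau_zero_all_distinct_gives_singletons(self):
        img = np.arange(16, dtype=np.uint8).reshape(4, 4)
        rmap = region_grow(img, [(0, 0), (3, 3)], tau=0.0)
        assert rmap.region_mask(1).sum() == 1
        assert rmap.region_mask(2).sum() == 1

    def test_matches_flood_fill_oracle_on_binary_blobs(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[1:4, 1:4] = 255
        img[6:9, 5:9] = 255
        rmap = region_grow(img, [(2, 2), (7, 7)], tau=0.0)

        def flood(seed):  # explicit stack-based oracle
            stack, seen = [seed], {seed}
            while stack:
                r, c = stack.pop()
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < 10
                        and 0 <= cc < 10
                        and (rr, cc) not in seen
                        and img[rr, cc] == img[seed]
                    ):
                        seen.add((rr, cc))
                        stack.append((rr, cc))
            return seen

        for k, seed in ((1, (2, 2)), (2, (7, 7))):
            got = set(map(tuple, np.argwhere(rmap.region_mask(k))))
            assert got == flood(seed)

    def test_out_of_bounds_seed_rejected(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(ValueError):
            region_grow(img, [(5, 0)], tau=1.0)

    def test_partition_invariants_and_reproducibility(self, rng):
        img = rng.integers(0, 256, size=(20, 20), dtype=np.uint8)
        seeds = [(2, 2), (10, 15), (17, 4)]
        a = region_grow(img, seeds, tau=30.0, connectivity=4)
        b = region_grow(img, seeds, tau=30.0, connectivity=4)
        np.testing.assert_array_equal(a.labels, b.labels)
        # pairwise disjoint by construction of the label array; connectedness:
        for k in range(1, a.n_regions + 1):
            mask = a.region_mask(k)
            if mask.any():
                _, n_comp = ndimage.label(mask)
                assert n_comp == 1


class TestSelectCandidate:
    def test_disk_beats_line(self):
        img = np.zeros((40, 40), dtype=np.uint8)
        yy, xx = np.mgrid[0:40, 0:40]
        disk = (yy - 12) ** 2 + (xx - 12) ** 2 <= 16
        img[disk] = 200
        img[30, 2:2 + disk.sum()] = 200  # line of equal area
        rmap = region_grow(img, [(12, 12), (30, 10)], tau=0.0)
        cand = select_candidate(rmap, img)
        assert cand.region_id == 1
        assert cand.circularity > 0

    def test_single_region_always_returned(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        img[2:5, 2:5] = 100
        rmap = region_grow(img, [(3, 3)], tau=0.0)
        cand = select_candidate(rmap, img)
        assert cand.region_id == 1

    def test_candidate_recovers_tumor(self, clean_tumor_spec):
        img, mask, _ = generate_phantom(clean_tumor_spec)
        part = fcm_fit_image(img, c=3, seed=0)
        seeds = select_seeds(part, img)
        rmap = region_grow(img, [(r, c) for r, c, _ in seeds], tau=5.0)
        cand = select_candidate(rmap, img)
        _, dice = segmentation_metrics(cand.mask, mask)
        assert dice >= 0.8


class TestSegmentationMetrics:
    def test_identity(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1:3, 1:3] = True
        assert segmentation_metrics(m, m) == (1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((5, 5), dtype=bool)
        b = np.zeros((5, 5), dtype=bool)
        a[0, 0] = True
        b[4, 4] = True
        _, dice = segmentation_metrics(a, b)
        assert dice == 0.0

    def test_half_overlap_by_direct_count(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a.ravel()[:50] = True
        b.ravel()[25:75] = True
        _, dice = segmentation_metrics(a, b)
        assert dice == 2 * 25 / (50 + 50)

    def test_empty_masks_dice_one(self):
        e = np.zeros((3, 3), dtype=bool)
        assert segmentation_metrics(e, e) == (1.0, 1.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            segmentation_metrics(np.zeros((2, 2), bool), np.zeros((3, 3), bool))
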