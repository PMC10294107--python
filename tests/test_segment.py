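"""Thresholding, localization, contact judgment and cluster separation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedseg import (
    ContactRule,
    DegenerateHistogramError,
    EmptyReferenceError,
    ParameterError,
    SeedBox,
    SeparationConfig,
    binarize,
    classify_touching,
    erode,
    locate_seeds,
    otsu_threshold,
    separate_eop,
    separate_wa,
)


def brute_force_otsu(hist):
    """Exhaustive scan of all 256 candidate thresholds."""
    hist = np.asarray(hist, float)
    total = hist.sum()
    best_t, best_v = None, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / hist[: t + 1].sum()
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / hist[t + 1 :].sum()
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_two_delta_histogram_splits_the_modes(self):
        hist = np.zeros(256)
        hist[50] = 300
        hist[200] = 500
        t = otsu_threshold(hist)
        assert 50 <= t < 200

    def test_equals_exhaustive_scan_on_random_histograms(self, rng):
        for _ in range(50):
            hist = np.zeros(256)
            lo = rng.normal(rng.uniform(40, 90), rng.uniform(5, 20), 400)
            hi = rng.normal(rng.uniform(150, 220), rng.uniform(5, 20), 300)
            vals = np.clip(np.concatenate([lo, hi]), 0, 255).astype(int)
            np.add.at(hist, vals, 1)
            assert otsu_threshold(hist) == brute_force_otsu(hist)

    def test_agrees_with_skimage_on_an_image(self, rng):
        from skimage.filters import threshold_otsu

        img = np.clip(
            np.concatenate([rng.normal(60, 10, 2000), rng.normal(190, 15, 1500)]), 0, 255
        ).astype(np.uint8)
        hist = np.bincount(img, minlength=256)
        t = otsu_threshold(hist)
        # skimage returns the same class split (its threshold is the bin edge)
        t_sk = threshold_otsu(hist=(hist, np.arange(256)))
        assert (img > t).sum() == (img > t_sk).sum()

    def test_single_bin_histogram_rejected(self):
        hist = np.zeros(256)
        hist[17] = 1000
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(hist)

    def test_malformed_histogram_rejected(self):
        with pytest.raises(ParameterError):
            otsu_threshold(np.zeros(100))


class TestBinarize:
    def test_recovers_generator_union_mask(self, small_scene):
        """Bright ellipses on a dark ground: the Otsu mask should equal the
        generator's union-of-seeds mask within 2% symmetric difference."""
        scene, truth = small_scene
        mask = binarize(scene)
        sym = np.count_nonzero(mask ^ truth.union_mask)
        union = np.count_nonzero(mask | truth.union_mask)
        assert sym / union <= 0.02

    def test_all_black_scene_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            binarize(np.zeros((16, 16, 3), dtype=np.uint8))

    def test_inverting_scene_and_polarity_gives_identical_mask(self, rng):
        gray = np.clip(
            np.concatenate([rng.normal(50, 8, 1800), rng.normal(200, 8, 1200)]), 0, 255
        ).astype(np.uint8).reshape(50, 60)
        scene = np.stack([gray] * 3, axis=-1)
        inverted = (255 - scene.astype(int)).astype(np.uint8)
        assert np.array_equal(binarize(scene, "bright"), binarize(inverted, "dark"))


def brute_force_components(mask):
    """Flood-fill component walk; returns (min/max coords, area) per component
    in row-major discovery order."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x] or seen[y, x]:
                continue
            stack = [(y, x)]
            seen[y, x] = True
            pix = []
            while stack:
                cy, cx = stack.pop()
                pix.append((cy, cx))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            ys = [p[0] for p in pix]
            xs = [p[1] for p in pix]
            comps.append((min(xs), min(ys), max(xs), max(ys), len(pix)))
    return comps


class TestLocateSeeds:
    def test_single_square(self):
        mask = np.zeros((30, 30), bool)
        mask[7:17, 5:15] = True
        (box,) = locate_seeds(mask)
        assert (box.x, box.y, box.w, box.h) == (5, 7, 10, 10)
        assert box.area == 100

    def test_two_squares_row_major_order(self):
        mask = np.zeros((40, 40), bool)
        mask[20:25, 2:7] = True
        mask[3:8, 30:35] = True
        boxes = locate_seeds(mask)
        assert [(b.x, b.y) for b in boxes] == [(30, 3), (2, 20)]

    def test_matches_brute_force_component_scan(self, rng):
        mask = np.zeros((64, 64), bool)
        for _ in range(50):
            y, x = rng.integers(0, 60, 2)
            mask[y : y + rng.integers(2, 5), x : x + rng.integers(2, 5)] = True
        boxes = locate_seeds(mask)
        comps = sorted(brute_force_components(mask), key=lambda c: (c[1], c[0]))
        assert len(boxes) == len(comps)
        for b, (x0, y0, x1, y1, area) in zip(
            sorted(boxes, key=lambda b: (b.y, b.x)), comps
        ):
            assert (b.x, b.y, b.w, b.h, b.area) == (x0, y0, x1 - x0 + 1, y1 - y0 + 1, area)

    def test_boxes_are_tight(self, rng):
        mask = rng.random((48, 48)) < 0.25
        for b in locate_seeds(mask):
            sub = mask[b.y : b.y + b.h, b.x : b.x + b.w]
            assert sub[0, :].any() and sub[-1, :].any()
            assert sub[:, 0].any() and sub[:, -1].any()

    def test_empty_mask(self):
        assert locate_seeds(np.zeros((10, 10), bool)) == []

    def test_min_area_filter(self):
        mask = np.zeros((20, 20), bool)
        mask[1:3, 1:3] = True  # area 4
        mask[10:16, 10:16] = True  # area 36
        assert len(locate_seeds(mask, min_area=10)) == 1


class TestClassifyTouching:
    def test_identical_boxes_none_flagged(self):
        boxes = [SeedBox(x=10 * i, y=0, w=5, h=5) for i in range(10)]
        assert not any(b.touching for b in classify_touching(boxes, ContactRule()))

    def test_single_oversized_box_flagged(self):
        boxes = [SeedBox(x=12 * i, y=0, w=10, h=10) for i in range(9)]
        boxes.append(SeedBox(x=120, y=0, w=15, h=15))  # area 2.25x the unit
        flags = [b.touching for b in classify_touching(boxes, ContactRule(area_ratio=1.5))]
        assert flags == [False] * 9 + [True]

    def test_generator_pairs_flagged(self, small_scene):
        scene, truth = small_scene
        mask = binarize(scene)
        boxes = classify_touching(locate_seeds(mask, min_area=16), ContactRule())
        n_pairs = len(truth.touching_pairs)
        assert len(boxes) == truth.n_seeds - n_pairs
        assert sum(b.touching for b in boxes) == n_pairs

    def test_empty_boxes_with_median_reference_rejected(self):
        with pytest.raises(EmptyReferenceError):
            classify_touching([], ContactRule())

    def test_invalid_ratios_rejected(self):
        with pytest.raises(ParameterError):
            ContactRule(area_ratio=1.0)


def brute_force_erode(mask, k):
    """Per-pixel neighborhood-AND with out-of-bounds counted as background."""
    mask = np.asarray(mask, bool)
    r = k // 2
    padded = np.pad(mask, r, mode="constant", constant_values=False)
    h, w = mask.shape
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            out[y, x] = padded[y : y + k, x : x + k].all()
    return out


class TestErode:
    def test_bridge_eliminated_between_two_squares(self):
        mask = np.zeros((60, 100), bool)
        mask[20:40, 10:30] = True
        mask[20:40, 50:70] = True
        mask[28:32, 30:50] = True  # 4-px-wide bridge
        out = erode(mask, 13)
        boxes = locate_seeds(out)
        assert len(boxes) == 2
        assert all((b.w, b.h) == (8, 8) for b in boxes)

    def test_object_thinner_than_kernel_vanishes(self):
        mask = np.zeros((40, 40), bool)
        mask[10:22, 10:22] = True  # 12x12 < 13
        assert not erode(mask, 13).any()

    def test_matches_brute_force_neighborhood_and(self, rng):
        mask = rng.random((32, 32)) < 0.6
        assert np.array_equal(erode(mask, 5), brute_force_erode(mask, 5))

    def test_kernel_one_is_identity(self, rng):
        mask = rng.random((16, 16)) < 0.5
        assert np.array_equal(erode(mask, 1), mask)

    def test_even_or_negative_kernel_rejected(self):
        for k in (0, -3, 4):
            with pytest.raises(ParameterError):
                erode(np.ones((5, 5), bool), k)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000), k1=st.sampled_from([1, 3, 5]), k2=st.sampled_from([1, 3, 5]))
    def test_anti_extensive_and_composable(self, seed, k1, k2):
        mask = np.random.default_rng(seed).random((24, 24)) < 0.7
        once = erode(mask, k1)
        assert not (once & ~mask).any()  # anti-extensive
        assert np.array_equal(erode(once, k2), erode(mask, k1 + k2 - 1))


def disks(shape, centers, radius):
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, bool)
    for cy, cx in centers:
        mask |= (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    return mask


class TestSeparateEop:
    def test_splits_tiny_contact_pair(self, pair_cluster):
        cluster, _ = pair_cluster
        boxes = separate_eop(cluster, SeparationConfig("EOP", 13))
        assert len(boxes) == 2
        assert not any(b.unseparated for b in boxes)

    def test_single_seed_passes_through(self):
        mask = disks((80, 80), [(40, 40)], 18)
        boxes = separate_eop(mask, SeparationConfig("EOP", 13))
        assert len(boxes) == 1

    def test_three_chained_seeds_give_three_boxes(self):
        mask = disks((80, 220), [(40, 40), (40, 110), (40, 180)], 22)
        mask[39:42, 40:110] = True  # two 3-px bridges
        mask[39:42, 110:180] = True
        boxes = separate_eop(mask, SeparationConfig("EOP", 13))
        assert len(boxes) == 3

    def test_fully_eroded_cluster_returned_unseparated(self):
        mask = np.zeros((30, 30), bool)
        mask[10:18, 10:18] = True  # 8x8 < 13
        boxes = separate_eop(mask, SeparationConfig("EOP", 13))
        assert len(boxes) == 1
        assert boxes[0].unseparated
        assert (boxes[0].x, boxes[0].y, boxes[0].w, boxes[0].h) == (10, 10, 8, 8)


class TestSeparateWa:
    def test_two_overlapping_disks_split_along_neck(self):
        mask = disks((80, 110), [(40, 40), (40, 70)], 18)
        boxes = separate_wa(mask, SeparationConfig("WA", wa_min_distance=15))
        assert len(boxes) == 2

    def test_single_disk_one_box(self):
        mask = disks((80, 80), [(40, 40)], 18)
        boxes = separate_wa(mask, SeparationConfig("WA", wa_min_distance=15))
        assert len(boxes) == 1
        assert not boxes[0].unseparated

    def test_basins_partition_cluster_foreground(self, pair_cluster):
        cluster, _ = pair_cluster
        boxes = separate_wa(cluster, SeparationConfig("WA", wa_min_distance=20))
        assert len(boxes) == 2
        assert sum(b.area for b in boxes) == int(cluster.sum())

    def test_missing_min_distance_rejected(self):
        with pytest.raises(ParameterError):
            separate_wa(np.ones((10, 10), bool), SeparationConfig("WA"))


def test_separation_config_validation():
    for kwargs in ({"method": "XX"}, {"kernel": 4}, {"kernel": 1}, {"wa_min_distance": -1.0}):
        with pytest.raises(ParameterError):
            SeparationConfig(**kwargs)
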