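import numpy as np
import pytest

from lungpaste.phantom import default_spec, generate_normal_phantom
from lungpaste.segmentation import (
    EmptyMaskWarning,
    SegmentationParams,
    binarize_otsu,
    clear_border,
    dilate,
    equalize_local_histogram,
    filter_components,
    morphological_open,
    otsu_threshold,
    segment_lungs,
)

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------


def flood_fill_components(mask):
    """8-connected components by BFS; returns a list of pixel-coordinate sets."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    components = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            queue, comp = [(r0, c0)], set()
            seen[r0, c0] = True
            while queue:
                r, c = queue.pop()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < mask.shape[0]
                            and 0 <= cc < mask.shape[1]
                            and mask[rr, cc]
                            and not seen[rr, cc]
                        ):
                            seen[rr, cc] = True
                            queue.append((rr, cc))
            components.append(comp)
    return components


def brute_clear_border(mask):
    out = np.asarray(mask, dtype=bool).copy()
    h, w = out.shape
    for comp in flood_fill_components(mask):
        if any(r in (0, h - 1) or c in (0, w - 1) for r, c in comp):
            for r, c in comp:
                out[r, c] = False
    return out


def brute_filter_components(mask, t):
    out = np.asarray(mask, dtype=bool).copy()
    for comp in flood_fill_components(mask):
        if len(comp) < t:
            for r, c in comp:
                out[r, c] = False
    return out


def brute_otsu_bin_split(counts):
    """Exhaustive scan over all 256 bin splits; returns the best split index."""
    centers = (np.arange(256) + 0.5) / 256
    best_k, best_var = None, -1.0
    total = counts.sum()
    for k in range(255):
        w0 = counts[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_k = var, k
    return best_k


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------


class TestEqualize:
    def test_constant_image_stays_uniform(self):
        out = equalize_local_histogram(np.full((64, 64), 0.5))
        assert out.shape == (64, 64)
        assert out.max() - out.min() <= 1 / 255

    def test_output_range_and_shape(self, phantom_256):
        out = equalize_local_histogram(phantom_256.image)
        assert out.shape == phantom_256.image.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_flattens_histogram(self):
        # low-contrast two-level image: equalization must spread the levels
        rng = np.random.default_rng(0)
        img = np.where(rng.random((64, 64)) < 0.5, 0.45, 0.55)
        out = equalize_local_histogram(img)
        assert out.std() > img.std()

    def test_lung_stays_darker_over_20_seeds(self):
        for seed in range(20):
            sample = generate_normal_phantom(default_spec(rng_seed=seed))
            eq = equalize_local_histogram(sample.image)
            assert eq[sample.lung_truth].mean() < eq[~sample.lung_truth].mean()

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            equalize_local_histogram(np.random.default_rng(0).random((4, 4)))


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------


class TestOtsu:
    def test_bimodal_toy(self):
        img = np.concatenate([np.full(18, 0.2), np.full(18, 0.8)]).reshape(6, 6)
        thr = otsu_threshold(img)
        assert 0.2 < thr <= 0.8
        mask = binarize_otsu(img, "dark_foreground")
        assert mask.sum() == 18
        assert np.array_equal(mask, img < 0.5)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            otsu_threshold(np.full((8, 8), 0.3))

    def test_polarity_complement(self):
        rng = np.random.default_rng(1)
        img = rng.random((16, 16))
        dark = binarize_otsu(img, "dark_foreground")
        bright = binarize_otsu(img, "bright_foreground")
        assert np.array_equal(dark, ~bright)

    def test_two_spike_histogram(self):
        # 100 pixels in bin 50, 100 in bin 200: split must match brute force
        vals = np.r_[np.full(100, 50.5 / 256), np.full(100, 200.5 / 256)]
        img = vals.reshape(10, 20)
        counts = np.zeros(256)
        counts[50], counts[200] = 100, 100
        k = brute_otsu_bin_split(counts)
        assert otsu_threshold(img) == pytest.approx((k + 1) / 256)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((12, 12))
        counts = np.bincount(
            np.minimum((img * 256).astype(int), 255).ravel(), minlength=256
        ).astype(float)
        k = brute_otsu_bin_split(counts)
        assert otsu_threshold(img) == pytest.approx((k + 1) / 256)

    def test_foreground_covers_lung_before_morphology(self):
        # noise-free phantoms: the Otsu dark class must capture the lung almost fully
        for seed in range(20):
            sample = generate_normal_phantom(default_spec(rng_seed=seed, noise_sigma=0.0))
            eq = equalize_local_histogram(sample.image)
            fg = binarize_otsu(eq, "dark_foreground")
            covered = (fg & sample.lung_truth).sum() / sample.lung_truth.sum()
            assert covered >= 0.95


# ---------------------------------------------------------------------------
# morphology and component ops
# ---------------------------------------------------------------------------


class TestMorphology:
    def test_opening_radius_zero_identity(self):
        rng = np.random.default_rng(2)
        mask = rng.random((10, 10)) < 0.4
        assert np.array_equal(morphological_open(mask, 0), mask)

    def test_opening_removes_isolated_pixel(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        assert not morphological_open(mask, 2).any()

    def test_opening_matches_brute_force_on_square_with_spur(self):
        def brute_open(mask, radius):
            offs = [
                (dr, dc)
                for dr in range(-radius, radius + 1)
                for dc in range(-radius, radius + 1)
                if dr * dr + dc * dc <= radius * radius
            ]
            h, w = mask.shape
            eroded = np.zeros_like(mask)
            for r in range(h):
                for c in range(w):
                    eroded[r, c] = all(
                        0 <= r + dr < h and 0 <= c + dc < w and mask[r + dr, c + dc]
                        for dr, dc in offs
                    )
            dilated = np.zeros_like(mask)
            for r in range(h):
                for c in range(w):
                    dilated[r, c] = any(
                        0 <= r + dr < h and 0 <= c + dc < w and eroded[r + dr, c + dc]
                        for dr, dc in offs
                    )
            return dilated

        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        mask[2:5, 15] = True  # 1-px wide protruding spur
        out = morphological_open(mask, 2)
        expected = brute_open(mask, 2)
        assert np.array_equal(out, expected)
        # the spur tip is gone and the square body survives
        assert not out[2:4, 15].any()
        assert out[8:22, 8:22].all()

    def test_dilation_radius_zero_identity(self):
        rng = np.random.default_rng(3)
        mask = rng.random((10, 10)) < 0.4
        assert np.array_equal(dilate(mask, 0), mask)

    def test_dilation_single_pixel_disc(self):
        # frozen fixture: Euclidean disc of radius 3 has 29 pixels
        mask = np.zeros((15, 15), dtype=bool)
        mask[7, 7] = True
        assert dilate(mask, 3).sum() == 29

    def test_dilation_extensive(self):
        rng = np.random.default_rng(4)
        mask = rng.random((20, 20)) < 0.2
        out = dilate(mask, 2)
        assert (out | mask).sum() == out.sum()
        assert out.sum() >= mask.sum()


class TestClearBorderAndFilter:
    def test_component_touching_top_removed(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0:3, 2:4] = True
        assert not clear_border(mask).any()

    def test_interior_blob_survives_corner_blob_removed(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4:6, 4:6] = True  # interior
        mask[0:2, 0:2] = True  # corner
        out = clear_border(mask)
        assert out[4:6, 4:6].all()
        assert out.sum() == 4

    def test_all_foreground_cleared(self):
        assert not clear_border(np.ones((6, 6), dtype=bool)).any()

    def test_filter_two_components(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, 0:3] = True  # size 3
        mask[4:6, 2:7] = True  # size 10
        out = filter_components(mask, 5)
        assert out.sum() == 10
        assert not out[0].any()

    def test_filter_t1_identity(self):
        rng = np.random.default_rng(5)
        mask = rng.random((12, 12)) < 0.3
        assert np.array_equal(filter_components(mask, 1), mask)

    def test_filter_t_above_area_empties(self):
        mask = np.ones((6, 6), dtype=bool)
        assert not filter_components(mask, 37).any()

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(3, 17, size=2)
        mask = rng.random((h, w)) < rng.uniform(0.2, 0.7)
        assert np.array_equal(clear_border(mask), brute_clear_border(mask))
        t = int(rng.integers(1, 12))
        assert np.array_equal(filter_components(mask, t), brute_filter_components(mask, t))

    def test_filter_idempotent(self):
        rng = np.random.default_rng(6)
        mask = rng.random((16, 16)) < 0.4
        once = filter_components(mask, 4)
        assert np.array_equal(filter_components(once, 4), once)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def dice(a, b):
    return 2 * (a & b).sum() / (a.sum() + b.sum())


class TestSegmentLungs:
    def test_dice_on_default_phantoms(self, segmented_phantoms_256):
        samples, masks = segmented_phantoms_256
        scores = [dice(m, s.lung_truth) for s, m in zip(samples, masks)]
        assert np.mean(scores) >= 0.8
        assert min(scores) >= 0.7

    def test_mask_contracts(self, segmented_phantoms_256):
        _, masks = segmented_phantoms_256
        params = SegmentationParams.for_image_size(256)
        for mask in masks:
            assert not mask[0].any() and not mask[-1].any()
            assert not mask[:, 0].any() and not mask[:, -1].any()
            labeled = flood_fill_components(mask)
            assert all(len(comp) >= params.t for comp in labeled)

    def test_all_bright_image_returns_empty_with_warning(self):
        # bright image with a smooth gradient: the darker side is a single
        # border-touching region, so nothing survives border clearing
        img = np.tile(np.linspace(0.7, 0.9, 64), (64, 1))
        with pytest.warns(EmptyMaskWarning):
            mask = segment_lungs(img, SegmentationParams.for_image_size(64))
        assert not mask.any()

    def test_monotone_in_t(self, phantom_256):
        base = SegmentationParams.for_image_size(256)
        small = segment_lungs(phantom_256.image, base)
        big_t = SegmentationParams.for_image_size(256, t=4 * base.t)
        large = segment_lungs(phantom_256.image, big_t)
        assert not (large & ~small).any()  # foreground(t2) subset of foreground(t1)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SegmentationParams(t=0)
        with pytest.raises(ValueError):
            SegmentationParams(opening_radius=-1)
        with pytest.raises(ValueError):
            SegmentationParams(otsu_polarity="sideways")
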