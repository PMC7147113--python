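"""Segmentation: DoG filtering, thresholding, component extraction."""

import numpy as np
import pytest

from flsquant import (
    ImageStack,
    SegmentationConfig,
    SyntheticStackConfig,
    dog_filter,
    extract_components,
    generate_fls_stack,
    segment_stack,
    threshold_slice,
)

from conftest import dense_dog_oracle


class TestDogFilter:
    def test_constant_image_maps_to_zero(self):
        img = np.full((32, 32), 7.3)
        out = dog_filter(img, 1.5, 3.0)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_impulse_matches_dense_convolution(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        out = dog_filter(img, 2.0, 4.0)
        ref = dense_dog_oracle(img, 2.0, 4.0)
        assert abs(out[32, 32] - ref[32, 32]) < 1e-6

    def test_random_images_match_dense_convolution(self, rng):
        for _ in range(5):
            img = rng.random((64, 64))
            out = dog_filter(img, 1.5, 3.0)
            ref = dense_dog_oracle(img, 1.5, 3.0)
            assert np.max(np.abs(out - ref)) < 1e-6

    def test_linearity(self, rng):
        img = rng.random((64, 64))
        a = dog_filter(3.7 * img, 1.5, 3.0)
        b = 3.7 * dog_filter(img, 1.5, 3.0)
        assert np.max(np.abs(a - b)) < 1e-9 * max(1.0, np.max(np.abs(b)))

    @pytest.mark.parametrize("sigmas", [(0, 2), (3, 2), (2, 2), (-1, 1)])
    def test_invalid_sigmas_rejected(self, sigmas):
        with pytest.raises(ValueError):
            dog_filter(np.zeros((8, 8)), *sigmas)


class TestThresholdSlice:
    def test_all_zero_image_gives_empty_mask(self):
        assert not threshold_slice(np.zeros((16, 16)), 3.0).any()

    def test_hand_computed_block_selection(self):
        # 96 zeros + a 2x2 block of 10: mean 0.4, population sd ~1.9596,
        # mean + 2 sd ~ 4.32, so exactly the block survives.
        img = np.zeros((10, 10))
        img[4:6, 4:6] = 10.0
        mask = threshold_slice(img, 2.0)
        expected = np.zeros((10, 10), dtype=bool)
        expected[4:6, 4:6] = True
        assert np.array_equal(mask, expected)

    def test_monotone_in_k(self, rng):
        for _ in range(10):
            img = rng.normal(size=(32, 32))
            loose = threshold_slice(img, 2.0)
            strict = threshold_slice(img, 4.0)
            assert not (strict & ~loose).any()

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            threshold_slice(np.zeros((0, 0)), 1.0)


class TestExtractComponents:
    def test_two_disjoint_squares(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[1:4, 1:4] = True
        mask[7:10, 7:10] = True
        comps = extract_components(mask, 0, min_area_px=1)
        assert len(comps) == 2
        assert all(c.area_px == 9 for c in comps)

    def test_min_area_filters_single_pixels(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert extract_components(mask, 0, min_area_px=2) == []

    def test_diagonal_pixels_join_under_8_connectivity(self):
        # Enumerated 2-pixel case: touching only at a corner.
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        comps = extract_components(mask, 0, min_area_px=1)
        assert len(comps) == 1
        assert comps[0].area_px == 2

    def test_intensity_weighted_centroid(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 0] = mask[1, 2] = mask[1, 1] = True
        intensity = np.zeros((3, 3))
        intensity[1, 0], intensity[1, 1], intensity[1, 2] = 1.0, 1.0, 2.0
        (comp,) = extract_components(mask, 0, 1, intensity_image=intensity)
        assert comp.centroid == pytest.approx((1.25, 1.0))

    def test_deterministic_ordering(self, rng):
        mask = rng.random((40, 40)) > 0.8
        a = extract_components(mask, 0, 1)
        b = extract_components(mask, 0, 1)
        assert a == b
        keys = [(c.centroid[1], c.centroid[0]) for c in a]
        assert keys == sorted(keys)


class TestSegmentStack:
    def test_single_vertical_filament_one_component_per_slice(self):
        cfg = SyntheticStackConfig(
            image_shape=(10, 64, 64), n_filaments=1, length_range=(9.0, 9.0),
            curvature_scale=0.0, noise_sd=0.0, background_level=0.0, seed=0,
        )
        stack, _ = generate_fls_stack(cfg)
        per_slice = segment_stack(stack)
        for z in range(10):
            assert len(per_slice[z]) == 1, f"slice {z}"

    def test_pure_background_mostly_empty(self):
        empty = 0
        total = 0
        for seed in range(50):
            cfg = SyntheticStackConfig(
                image_shape=(2, 64, 64), n_filaments=0, length_range=(1.0, 1.0),
                background_level=100.0, noise_sd=20.0, seed=seed,
            )
            stack, truth = generate_fls_stack(cfg)
            assert truth == []
            for comps in segment_stack(stack):
                total += 1
                empty += not comps
        assert empty / total >= 0.95

    def test_repeated_segmentation_identical(self, rng):
        stack = ImageStack(rng.random((4, 32, 32)), 0.1, 1.0)
        assert segment_stack(stack) == segment_stack(stack)

    def test_translation_equivariance(self):
        cfg = SyntheticStackConfig(
            image_shape=(3, 96, 96), n_filaments=1, length_range=(2.0, 2.0),
            curvature_scale=0.0, noise_sd=0.0, background_level=0.0, seed=4,
        )
        stack, _ = generate_fls_stack(cfg)
        img = stack.voxels[0]
        shifted = np.roll(img, (5, 9), axis=(0, 1))
        comps = extract_components(
            threshold_slice(dog_filter(img, 1.5, 3.0), 3.0), 0, 4, img
        )
        comps_shifted = extract_components(
            threshold_slice(dog_filter(shifted, 1.5, 3.0), 3.0), 0, 4, shifted
        )
        assert len(comps) == len(comps_shifted) == 1
        dx = comps_shifted[0].centroid[0] - comps[0].centroid[0]
        dy = comps_shifted[0].centroid[1] - comps[0].centroid[1]
        assert (dx, dy) == pytest.approx((9.0, 5.0), abs=1e-6)


def test_segmentation_config_validation():
    with pytest.raises(ValueError):
        SegmentationConfig(sigma_small=3.0, sigma_large=1.5)
    with pytest.raises(ValueError):
        SegmentationConfig(min_area_px=0)
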