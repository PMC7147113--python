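"""Synthetic generators: determinism, ground-truth consistency, structure."""

import math

import numpy as np
import pandas as pd
import pytest

from flsquant import (
    FilamentSpec,
    LinescanDatasetConfig,
    SyntheticStackConfig,
    generate_fls_stack,
    generate_linescan_dataset,
    generate_phenotype_conditions,
)


class TestFilamentSpec:
    def test_straight_line_truth(self):
        f = FilamentSpec((5.0, 5.0), 0.5, ((5.0, 5.0, 0.0), (5.0, 5.0, 10.0)), 100.0)
        assert f.arc_length_um == pytest.approx(10.0)
        assert f.straightness_true == pytest.approx(1.0)

    def test_helical_polyline_matches_hand_summation(self):
        pts = tuple(
            (5 + math.cos(0.5 * z), 5 + math.sin(0.5 * z), float(z))
            for z in range(11)
        )
        f = FilamentSpec((6.0, 5.0), 0.5, pts, 100.0)
        expected = sum(
            math.sqrt(
                (pts[i + 1][0] - pts[i][0]) ** 2
                + (pts[i + 1][1] - pts[i][1]) ** 2
                + (pts[i + 1][2] - pts[i][2]) ** 2
            )
            for i in range(10)
        )
        assert f.arc_length_um == pytest.approx(expected, rel=1e-12)
        assert f.arc_length_um >= math.dist(pts[0], pts[-1])

    @pytest.mark.parametrize(
        "polyline",
        [
            (((0.0, 0.0, 0.0)),),  # single point
            ((0.0, 0.0, 1.0), (0.0, 0.0, 2.0)),  # does not start at z=0
            ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),  # z not strictly increasing
        ],
    )
    def test_invalid_polylines_rejected(self, polyline):
        with pytest.raises(ValueError):
            FilamentSpec((0.0, 0.0), 0.5, tuple(polyline), 100.0)


class TestStackGeneration:
    def test_zero_filaments_gives_background_only(self):
        cfg = SyntheticStackConfig(image_shape=(3, 32, 32), n_filaments=0,
                                   length_range=(1.0, 2.0), seed=1)
        stack, truth = generate_fls_stack(cfg)
        assert truth == []
        assert abs(stack.voxels.mean() - cfg.background_level) < 5.0

    def test_same_seed_bit_identical(self):
        cfg = SyntheticStackConfig(image_shape=(6, 64, 64), n_filaments=3,
                                   length_range=(3.0, 5.0), min_separation_um=1.5, seed=9)
        s1, t1 = generate_fls_stack(cfg)
        s2, t2 = generate_fls_stack(cfg)
        assert np.array_equal(s1.voxels, s2.voxels)
        assert t1 == t2

    def test_truth_consistency(self):
        cfg = SyntheticStackConfig(seed=3)
        _, truth = generate_fls_stack(cfg)
        assert len(truth) == cfg.n_filaments
        for rec in truth:
            assert 0 < rec.straightness_true <= 1
            assert rec.base_area_um2 > 0

    def test_rasterization_fidelity(self):
        # No noise, no blur: the brightest base-slice pixel sits within one
        # base radius of the true base centroid.
        cfg = SyntheticStackConfig(
            image_shape=(5, 64, 64), n_filaments=1, length_range=(4.0, 4.0),
            psf_sigma_xy=0.0, noise_sd=0.0, background_level=0.0, seed=5,
        )
        stack, (rec,) = generate_fls_stack(cfg)
        row, col = np.unravel_index(np.argmax(stack.voxels[0]), stack.voxels[0].shape)
        dist_px = math.hypot(col - rec.base_centroid_px[0], row - rec.base_centroid_px[1])
        assert dist_px <= 0.6 / cfg.pixel_size_xy

    def test_min_separation_respected(self):
        cfg = SyntheticStackConfig(seed=11)
        _, truth = generate_fls_stack(cfg)
        px = cfg.pixel_size_xy
        for i, a in enumerate(truth):
            for b in truth[i + 1:]:
                d_um = px * math.hypot(
                    a.base_centroid_px[0] - b.base_centroid_px[0],
                    a.base_centroid_px[1] - b.base_centroid_px[1],
                )
                assert d_um >= cfg.min_separation_um - 1e-9

    def test_impossible_packing_rejected(self):
        cfg = SyntheticStackConfig(
            image_shape=(5, 32, 32), n_filaments=50, min_separation_um=3.0,
            length_range=(2.0, 4.0), seed=0,
        )
        with pytest.raises(ValueError):
            generate_fls_stack(cfg)

    def test_length_exceeding_stack_rejected(self):
        with pytest.raises(ValueError):
            SyntheticStackConfig(image_shape=(5, 64, 64), length_range=(3.0, 10.0))

    def test_zero_curvature_gives_straight_filaments(self):
        cfg = SyntheticStackConfig(
            image_shape=(12, 64, 64), n_filaments=2, curvature_scale=0.0,
            length_range=(8.0, 11.0), min_separation_um=1.5, seed=2,
        )
        _, truth = generate_fls_stack(cfg)
        for rec in truth:
            assert rec.straightness_true == pytest.approx(1.0)


class TestLinescanGeneration:
    def test_extreme_fractions(self):
        for frac, expect in [(1.0, True), (0.0, False)]:
            cfg = LinescanDatasetConfig(
                n_filopodia=30, positive_fraction=frac, positive_delta=500.0, seed=2
            )
            _, labels = generate_linescan_dataset(cfg)
            assert all(v is expect for v in labels.values())

    def test_label_count_matches_independent_bernoulli_draw(self):
        cfg = LinescanDatasetConfig(n_filopodia=400, positive_fraction=0.7, seed=13)
        _, labels = generate_linescan_dataset(cfg)
        expected = int((np.random.default_rng(13).random(400) < 0.7).sum())
        assert sum(labels.values()) == expected

    def test_pairing_and_determinism(self):
        cfg = LinescanDatasetConfig(n_filopodia=50, seed=4)
        scans1, labels1 = generate_linescan_dataset(cfg)
        scans2, labels2 = generate_linescan_dataset(cfg)
        assert scans1 == scans2
        assert labels1 == labels2
        assert sum(s.role == "filopodium" for s in scans1) == 50
        assert sum(s.role == "background" for s in scans1) == 50

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            LinescanDatasetConfig(positive_fraction=1.2)


class TestPhenotypeConditions:
    def test_row_count_arithmetic(self):
        df = generate_phenotype_conditions(
            23, 12, [0] * 23, {0: (0.0, 0.0, 0.0)}, seed=0
        )
        assert len(df) == 23 * 2 * 12

    def test_null_effects_keep_groups_exchangeable(self):
        df = generate_phenotype_conditions(
            6, 14, [0] * 6, {0: (0.0, 0.0, 0.0)}, noise_sd=1.0, seed=1
        )
        means = df.groupby("condition")["mean_length_um"].mean()
        assert means.max() - means.min() < 2.0  # sampling noise only

    def test_negative_length_shift_is_minimum_in_expectation(self):
        # Monte Carlo over 100 seeds: the shifted condition's median length
        # is the minimum among conditions in a clear majority of draws.
        wins = 0
        for seed in range(100):
            df = generate_phenotype_conditions(
                5, 10, [0, 0, 0, 0, 1], {0: (0, 0, 0), 1: (0.0, -4.0, 0.0)},
                noise_sd=1.0, seed=seed,
            )
            med = df.groupby("condition")["mean_length_um"].median()
            wins += med.idxmin() == "scFv04"
        assert wins >= 95

    def test_cluster_assignment_mismatch_rejected(self):
        with pytest.raises(ValueError):
            generate_phenotype_conditions(5, 10, [0, 0], {0: (0, 0, 0)})

    def test_both_actin_states_present(self):
        df = generate_phenotype_conditions(4, None, [0] * 4, {0: (0, 0, 0)}, seed=6)
        states = df.groupby("condition")["actin_state"].nunique()
        assert (states == 2).all()
        regions = df.groupby(["condition", "actin_state"]).size()
        assert regions.between(10, 17).all()
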