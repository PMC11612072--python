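"""Entropy maps, adaptive patch planning, corruption, RMSE and head swap."""

import numpy as np
import pytest

from segpretext.io_preprocess import InvalidInputError
from segpretext.nn import conv_layer_count
from segpretext.selflearn import (
    corrupt_image,
    InpaintPatchSpec,
    adapt_head,
    build_backbone,
    local_entropy,
    mean_fill_rmse,
    patch_size_mm,
    plan_inpainting_patches,
    pretrain_inpainting,
    rmse_loss,
    rmse_loss_grad,
)


class TestLocalEntropy:
    def test_constant_image_zero_entropy(self):
        emap = local_entropy(np.full((20, 20), 0.7), window_px=5)
        np.testing.assert_array_equal(emap.values, 0.0)

    def test_checkerboard_one_bit(self):
        board = np.indices((16, 16)).sum(axis=0) % 2 * 0.9
        emap = local_entropy(board, window_px=5, bins=8, smooth_sigma=0)
        # interior windows hold both values in near-equal counts:
        # 13/25 vs 12/25 -> H = -(13/25)log2(13/25) - (12/25)log2(12/25)
        p = 13 / 25
        expected = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
        np.testing.assert_allclose(emap.values[4:12, 4:12], expected, atol=1e-9)

    def test_bounded_by_log2_bins(self, one_slice):
        emap = local_entropy(one_slice.image, window_px=9, bins=32)
        assert emap.values.max() <= np.log2(32) + 1e-12
        assert emap.values.min() >= 0.0

    def test_even_window_rejected(self):
        with pytest.raises(InvalidInputError):
            local_entropy(np.zeros((10, 10)), window_px=8)


class TestPatchPlanning:
    def test_size_formula_endpoints(self):
        assert patch_size_mm(0.0, 5.0) == 25.0
        assert patch_size_mm(5.0, 5.0) == 3.0
        assert patch_size_mm(2.5, 5.0) == pytest.approx(14.0)

    def test_entropy_monotonicity_over_many_plans(self, textured_slice):
        """More and smaller patches in high-entropy regions, fewer and larger
        in flat regions."""
        emap = local_entropy(textured_slice.image)
        q = np.quantile(emap.values, [0.25, 0.75])
        rng = np.random.default_rng(9)
        sizes_low, sizes_high = [], []
        n_low = n_high = 0
        for _ in range(500):
            for spec in plan_inpainting_patches(emap, coverage=0.15, rng=rng):
                h_at = emap.values[spec.center]
                if h_at <= q[0]:
                    sizes_low.append(spec.size_mm)
                    n_low += 1
                elif h_at >= q[1]:
                    sizes_high.append(spec.size_mm)
                    n_high += 1
        assert np.mean(sizes_high) < np.mean(sizes_low)
        assert n_high > n_low
        assert all(3.0 <= s <= 25.0 for s in sizes_low + sizes_high)

    def test_coverage_reached_and_bounded(self, textured_slice):
        emap = local_entropy(textured_slice.image)
        plan = plan_inpainting_patches(emap, coverage=0.15, rng=3)
        cor = corrupt_image(textured_slice, plan)
        frac = cor.hole_mask.mean()
        assert 0.15 <= frac <= 0.15 + 25 * 25 / emap.values.size

    def test_zero_entropy_uniform_fallback(self):
        emap = local_entropy(np.full((40, 40), 0.3), window_px=5)
        plan = plan_inpainting_patches(emap, coverage=0.1, rng=4)
        assert len(plan) >= 1
        assert all(s.size_mm == 25.0 for s in plan)

    def test_reproducible(self, textured_slice):
        emap = local_entropy(textured_slice.image)
        p1 = plan_inpainting_patches(emap, rng=11)
        p2 = plan_inpainting_patches(emap, rng=11)
        assert [(s.center, s.size_mm) for s in p1] == [(s.center, s.size_mm) for s in p2]

    def test_bad_coverage_rejected(self, textured_slice):
        emap = local_entropy(textured_slice.image)
        with pytest.raises(InvalidInputError):
            plan_inpainting_patches(emap, coverage=0.7, rng=0)


class TestCorruption:
    def test_single_3mm_patch_is_3x3_hole(self, textured_slice):
        cor = corrupt_image(textured_slice, [InpaintPatchSpec((40, 40), 3.0)])
        assert cor.hole_mask.sum() == 9
        assert cor.hole_mask[39:42, 39:42].all()

    def test_overlapping_patches_union(self, textured_slice):
        plan = [InpaintPatchSpec((40, 40), 5.0), InpaintPatchSpec((41, 41), 5.0)]
        cor = corrupt_image(textured_slice, plan)
        assert set(np.unique(cor.hole_mask)) <= {0, 1}
        assert cor.hole_mask.sum() < 2 * 25  # overlap not double-counted

    def test_reconstruction_identity(self, textured_slice):
        cor = corrupt_image(textured_slice, [InpaintPatchSpec((30, 50), 9.0)])
        np.testing.assert_array_equal(
            cor.corrupted + cor.original * cor.hole_mask, cor.original)

    def test_empty_plan_rejected(self, textured_slice):
        with pytest.raises(InvalidInputError):
            corrupt_image(textured_slice, [])


class TestRmse:
    def test_perfect_prediction_zero(self):
        img = np.random.default_rng(0).random((8, 8))
        hole = np.zeros((8, 8), np.uint8)
        hole[2:4, 2:4] = 1
        assert rmse_loss(img, img, hole) == 0.0

    def test_constant_error_closed_form(self):
        img = np.zeros((8, 8))
        pred = img.copy()
        hole = np.zeros((8, 8), np.uint8)
        hole[1:5, 1:5] = 1
        pred[hole == 1] = -0.3
        assert rmse_loss(pred, img, hole) == pytest.approx(0.3)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        pred, orig = rng.random((8, 8)), rng.random((8, 8))
        hole = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        expected = np.sqrt(sum((pred[i, j] - orig[i, j]) ** 2
                               for i in range(8) for j in range(8) if hole[i, j])
                           / hole.sum())
        assert rmse_loss(pred, orig, hole) == pytest.approx(expected, abs=1e-12)

    def test_grad_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        pred, orig = rng.random((5, 5)), rng.random((5, 5))
        hole = np.zeros((5, 5), np.uint8)
        hole[1:4, 1:4] = 1
        _, g = rmse_loss_grad(pred, orig, hole)
        eps = 1e-6
        for i, j in [(1, 1), (2, 3), (0, 0)]:
            pp, pm = pred.copy(), pred.copy()
            pp[i, j] += eps
            pm[i, j] -= eps
            num = (rmse_loss(pp, orig, hole) - rmse_loss(pm, orig, hole)) / (2 * eps)
            assert g[i, j] == pytest.approx(num, abs=1e-6)

    def test_empty_hole_rejected(self):
        with pytest.raises(InvalidInputError):
            rmse_loss(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 4)))


class TestBackboneAndHeadSwap:
    def test_default_depth_is_twenty_convs(self):
        model = build_backbone(rng=0)
        assert conv_layer_count(model) == 20

    def test_head_swap_retains_trunk_bit_exactly(self):
        model = build_backbone(layers=6, width=4, rng=0)
        trunk_before = [p.value.copy() for p in model.trunk_params()]
        seg = adapt_head(model, rng=1)
        assert seg.head_kind == "softmax" and seg.out_ch == 2
        for b, p in zip(trunk_before, seg.trunk_params()):
            np.testing.assert_array_equal(b, p.value)

    def test_new_head_differs_across_seeds(self):
        model = build_backbone(layers=6, width=4, rng=0)
        h1 = adapt_head(model, rng=1).head_conv.W.value
        h2 = adapt_head(model, rng=2).head_conv.W.value
        assert not np.array_equal(h1, h2)

    def test_adapt_softmax_is_noop_with_warning(self, caplog):
        model = build_backbone(layers=6, width=4, head="softmax", rng=0)
        import logging

        with caplog.at_level(logging.WARNING):
            out = adapt_head(model)
        assert out is model
        assert any("no-op" in r.message for r in caplog.records)

    def test_architecture_signature_preserved(self):
        pre = build_backbone(layers=8, width=4, rng=0)
        seg = adapt_head(pre, rng=1)
        fresh = build_backbone(layers=8, width=4, head="softmax", rng=2)
        assert [p.value.shape for p in seg.params()] == [p.value.shape for p in fresh.params()]


class TestPretrainInpainting:
    def test_beats_mean_fill_baseline(self, small_cohort):
        samples = [s for v in small_cohort.values() for s in v]
        model = build_backbone(layers=6, width=8, rng=np.random.default_rng(0))
        model, history = pretrain_inpainting(model, samples, steps=200, batch=8, rng=1)
        baseline = mean_fill_rmse(samples, rng=2)
        assert np.mean(history[-10:]) < baseline
        assert history[-1] < history[0]

    def test_loss_history_and_smoothed_curve(self, small_cohort):
        from segpretext.selflearn import monotone_smoothed, plateau_reached

        samples = [s for v in small_cohort.values() for s in v]
        model = build_backbone(layers=4, width=4, rng=np.random.default_rng(0))
        model, history = pretrain_inpainting(model, samples, steps=30, batch=4,
                                             crop_px=48, rng=1)
        assert len(history) == 30
        curve = monotone_smoothed(history)
        assert (np.diff(curve) <= 1e-12).all()  # non-increasing by construction
        # a flat loss history triggers the plateau detector
        assert plateau_reached([1.0] * 40, patience=10)
        assert not plateau_reached(list(np.linspace(1.0, 0.0, 40)), patience=10)

    def test_early_stopping_on_plateau(self, small_cohort):
        samples = [s for v in small_cohort.values() for s in v]
        model = build_backbone(layers=4, width=4, rng=np.random.default_rng(0))
        # a plateau patience much smaller than the step budget stops early
        model, history = pretrain_inpainting(model, samples, steps=400, batch=4,
                                             crop_px=48, patience=5, rng=1)
        assert len(history) < 400

    def test_requires_sigmoid_head(self, small_cohort):
        samples = [s for v in small_cohort.values() for s in v]
        model = build_backbone(layers=4, width=4, head="softmax", rng=0)
        with pytest.raises(InvalidInputError):
            pretrain_inpainting(model, samples, steps=1)
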