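"""Patch sampling, pair construction, contrastive loss and encoder transfer."""

import numpy as np
import pytest

from segpretext.contrastive import (
    CannotFormNegativePairsError,
    ContrastiveEncoder,
    EmbeddingPair,
    PatchPair,
    RoiPatch,
    build_pair_batch,
    contrastive_loss,
    contrastive_loss_grad,
    pretrain_contrastive,
    sample_roi_patch,
    transfer_encoder,
)
from segpretext.io_preprocess import InvalidInputError, SliceSample


class TestSampleRoiPatch:
    def test_patch_shape_and_padding_at_corner(self):
        img = np.ones((40, 40))
        msk = np.zeros((40, 40), dtype=np.uint8)
        msk[0, 0] = 1  # mask touches the corner: crop must zero-pad
        s = SliceSample(img, msk, "p", 0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            patch = sample_roi_patch(s, rng)
            assert patch.pixels.shape == (30, 30)
        # interior draw centered at (0,0): upper-left quadrant is padding
        assert patch.pixels.sum() <= 30 * 30

    def test_single_voxel_mask_support(self):
        img = np.zeros((64, 64))
        msk = np.zeros((64, 64), dtype=np.uint8)
        msk[30, 30] = 1
        s = SliceSample(img, msk, "p", 0)
        rng = np.random.default_rng(1)
        for _ in range(50):
            patch = sample_roi_patch(s, rng, band_mm=10)
            d = np.hypot(patch.center[0] - 30, patch.center[1] - 30)
            assert d <= 10.0 + 1e-9

    def test_interior_fraction_near_half(self, one_slice):
        rng = np.random.default_rng(2)
        mask = one_slice.mask.astype(bool)
        n = 4000
        inside = sum(mask[sample_roi_patch(one_slice, rng).center] for _ in range(n))
        # binomial: sd of the fraction at n=4000 is ~0.008; allow 4 sd
        assert abs(inside / n - 0.5) < 0.032

    def test_empty_mask_raises(self):
        s = SliceSample(np.zeros((40, 40)), np.zeros((40, 40), np.uint8), "p", 0)
        with pytest.raises(InvalidInputError):
            sample_roi_patch(s, np.random.default_rng(0))


class TestPairBatch:
    def test_balanced_labels_and_consistency(self, small_cohort):
        rng = np.random.default_rng(3)
        pairs = build_pair_batch(small_cohort, 50, rng)
        labels = [p.label for p in pairs]
        assert sum(labels) == 25 and len(pairs) == 50
        for p in pairs:
            assert p.label == int(p.a.subject_id == p.b.subject_id)

    def test_two_subject_batch_of_two(self, small_cohort):
        two = {k: small_cohort[k] for k in list(small_cohort)[:2]}
        pairs = build_pair_batch(two, 2, np.random.default_rng(4))
        assert sorted(p.label for p in pairs) == [0, 1]

    def test_single_subject_rejected(self, small_cohort):
        one = {k: small_cohort[k] for k in list(small_cohort)[:1]}
        with pytest.raises(CannotFormNegativePairsError):
            build_pair_batch(one, 4, np.random.default_rng(0))

    def test_reproducible_with_fixed_seed(self, small_cohort):
        p1 = build_pair_batch(small_cohort, 10, np.random.default_rng(7))
        p2 = build_pair_batch(small_cohort, 10, np.random.default_rng(7))
        for a, b in zip(p1, p2):
            assert a.label == b.label and a.a.center == b.a.center
            np.testing.assert_array_equal(a.b.pixels, b.b.pixels)

    def test_inconsistent_label_rejected(self):
        pa = RoiPatch(np.zeros((30, 30)), "s1", (0, 0))
        pb = RoiPatch(np.zeros((30, 30)), "s2", (0, 0))
        with pytest.raises(InvalidInputError):
            PatchPair(pa, pb, 1)


class TestContrastiveLoss:
    def test_positive_identical_contributes_zero(self):
        p = np.ones((1, 4))
        for mode in ("corrected", "as_printed"):
            assert contrastive_loss(p, p, [1], mode=mode) == 0.0

    def test_negative_beyond_margin_zero_in_corrected(self):
        p1 = np.zeros((1, 4))
        p2 = np.full((1, 4), 2.0)  # distance 4 > margin 1
        assert contrastive_loss(p1, p2, [0], margin=1.0, mode="corrected") == 0.0

    def test_as_printed_is_label_independent(self):
        rng = np.random.default_rng(5)
        p1, p2 = rng.normal(size=(6, 8)), rng.normal(size=(6, 8))
        d2 = ((p1 - p2) ** 2).sum()
        for labels in ([1] * 6, [0] * 6, [1, 0, 1, 0, 1, 0]):
            assert contrastive_loss(p1, p2, labels, mode="as_printed") == pytest.approx(d2)

    def test_corrected_zero_iff_satisfied(self):
        p1 = np.array([[0.0, 0.0], [0.0, 0.0]])
        p2 = np.array([[0.0, 0.0], [1.5, 0.0]])
        assert contrastive_loss(p1, p2, [1, 0], margin=1.0) == 0.0
        # violate: negative pair inside the margin
        p2[1, 0] = 0.5
        assert contrastive_loss(p1, p2, [1, 0], margin=1.0) == pytest.approx(0.25)

    def test_permutation_and_swap_invariance(self):
        rng = np.random.default_rng(6)
        p1, p2 = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        labels = np.array([1, 0, 1, 0, 0])
        base = contrastive_loss(p1, p2, labels)
        perm = rng.permutation(5)
        assert contrastive_loss(p1[perm], p2[perm], labels[perm]) == pytest.approx(base)
        assert contrastive_loss(p2, p1, labels) == pytest.approx(base)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        p1, p2 = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        labels = [1, 0, 1, 0]
        _, g1, _ = contrastive_loss_grad(p1, p2, labels)
        eps = 1e-6
        for i in range(4):
            for j in range(3):
                pp = p1.copy()
                pp[i, j] += eps
                pm = p1.copy()
                pm[i, j] -= eps
                num = (contrastive_loss(pp, p2, labels) - contrastive_loss(pm, p2, labels)) / (2 * eps)
                assert g1[i, j] == pytest.approx(num, abs=1e-5)

    def test_accepts_embedding_pair_list(self):
        rng = np.random.default_rng(8)
        p1, p2 = rng.normal(size=(4, 5)), rng.normal(size=(4, 5))
        labels = [1, 0, 0, 1]
        pairs = [EmbeddingPair(a, b) for a, b in zip(p1, p2)]
        assert contrastive_loss(pairs, labels) == pytest.approx(
            contrastive_loss(p1, p2, labels))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            EmbeddingPair(np.zeros(3), np.zeros(4))
        with pytest.raises(InvalidInputError):
            contrastive_loss(np.zeros((2, 3)), np.zeros((2, 4)), [1, 0])


class TestPretrainAndTransfer:
    def test_separable_cohort_loss_decreases(self):
        # two subjects with disjoint constant intensities: trivially separable
        def subject(sid, level):
            img = np.full((48, 48), level)
            msk = np.zeros((48, 48), np.uint8)
            msk[16:32, 16:32] = 1
            return [SliceSample(img, msk, sid, 0)]

        cohort = {"lo": subject("lo", 0.1), "hi": subject("hi", 0.9)}
        for seed in (0, 1, 2):
            enc = ContrastiveEncoder(layers=4, width=4, embed_dim=8,
                                     rng=np.random.default_rng(seed))
            pairs0 = build_pair_batch(cohort, 16, np.random.default_rng(seed))
            za = enc.embed(np.stack([p.a.pixels for p in pairs0])[:, None])
            zb = enc.embed(np.stack([p.b.pixels for p in pairs0])[:, None])
            loss0 = contrastive_loss(za, zb, [p.label for p in pairs0]) / len(pairs0)
            enc, history = pretrain_contrastive(enc, cohort, steps=200, batch=16,
                                                rng=np.random.default_rng(seed + 100))
            assert np.mean(history[-10:]) < loss0

    def test_transfer_copies_encoder_and_fresh_decoder(self, small_cohort):
        enc = ContrastiveEncoder(layers=6, width=4, embed_dim=8, rng=np.random.default_rng(0))
        model = transfer_encoder(enc, rng=np.random.default_rng(1))
        for pe, pm in zip(enc.encoder.params(), model.encoder.params()):
            np.testing.assert_array_equal(pe.value, pm.value)
        m2 = transfer_encoder(enc, rng=np.random.default_rng(2))
        # decoders differ across seeds (fresh random init)
        assert any(not np.array_equal(a.value, b.value)
                   for a, b in zip(model.decoder.params(), m2.decoder.params()))

    def test_unfrozen_encoder_moves_on_training(self, small_cohort):
        from segpretext.experiment import train_segmentation

        enc = ContrastiveEncoder(layers=6, width=4, embed_dim=8, rng=np.random.default_rng(0))
        model = transfer_encoder(enc, freeze=False, rng=np.random.default_rng(1))
        before = [p.value.copy() for p in model.encoder.params()]
        samples = [s for v in small_cohort.values() for s in v]
        train_segmentation(model, samples, steps=2, batch=2, crop_px=32, rng=0)
        assert any(not np.array_equal(b, p.value)
                   for b, p in zip(before, model.encoder.params()))

    def test_frozen_encoder_fixed(self, small_cohort):
        from segpretext.experiment import train_segmentation

        enc = ContrastiveEncoder(layers=6, width=4, embed_dim=8, rng=np.random.default_rng(0))
        model = transfer_encoder(enc, freeze=True, rng=np.random.default_rng(1))
        before = [p.value.copy() for p in model.encoder.params()]
        samples = [s for v in small_cohort.values() for s in v]
        train_segmentation(model, samples, steps=2, batch=2, crop_px=32, rng=0)
        for b, p in zip(before, model.encoder.params()):
            np.testing.assert_array_equal(b, p.value)
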