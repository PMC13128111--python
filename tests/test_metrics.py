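"""Overlap metrics, surface-distance metrics, and the training objective.

Surface distances are verified against exhaustive all-pairs nearest-point
oracles on small boundary sets, and boundary extraction against a literal
per-voxel neighbour scan.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridseg import nn
from hybridseg.metrics import (LossWeights, asd, assd, boundary_points,
                               combined_loss, confusion_matrix,
                               cross_entropy_loss, dice_coefficient,
                               evaluate_case, hd95, soft_dice_loss)


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------


class TestDice:
    def test_identity_is_one(self):
        x = np.zeros((5, 5), bool)
        x[1:4, 1:4] = True
        assert dice_coefficient(x, x) == 1.0

    def test_disjoint_is_zero(self):
        x = np.zeros((4, 4), bool)
        y = np.zeros((4, 4), bool)
        x[0, 0] = True
        y[3, 3] = True
        assert dice_coefficient(x, y) == 0.0

    def test_half_overlap(self):
        x = np.zeros(8, bool)
        y = np.zeros(8, bool)
        x[:4] = True          # |X| = 4
        y[2:6] = True         # |Y| = 4, overlap 2
        assert dice_coefficient(x, y) == 0.5

    def test_both_empty_convention(self):
        z = np.zeros((3, 3), bool)
        assert dice_coefficient(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            dice_coefficient(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((6, 6)) > 0.5
        y = rng.random((6, 6)) > 0.5
        assert dice_coefficient(x, y) == dice_coefficient(y, x)


# ---------------------------------------------------------------------------
# training objective
# ---------------------------------------------------------------------------


class TestCombinedLoss:
    def _labels(self, rng, b=2, k=3, s=8):
        return rng.integers(0, k, size=(b, s, s))

    def test_perfect_prediction_drives_loss_to_zero(self, rng):
        labels = self._labels(rng)
        onehot = np.moveaxis(np.eye(3, dtype=np.float32)[labels], -1, 1)
        logits = nn.Tensor(40.0 * onehot)
        loss = combined_loss(logits, labels, LossWeights(0.5, 0.5)).item()
        assert 0.0 <= loss < 1e-3

    def test_zero_dice_weight_leaves_cross_entropy(self, rng):
        labels = self._labels(rng)
        logits = nn.Tensor(rng.normal(size=(2, 3, 8, 8)).astype(np.float32))
        combo = combined_loss(logits, labels, LossWeights(0.0, 1.0)).item()
        ce = cross_entropy_loss(logits, labels).item()
        assert combo == pytest.approx(ce, rel=1e-6)

    def test_uniform_logits_balanced_binary_gives_ln2(self):
        labels = np.array([[[0, 1], [1, 0]]])
        logits = nn.Tensor(np.zeros((1, 2, 2, 2), dtype=np.float32))
        assert cross_entropy_loss(logits, labels).item() == \
            pytest.approx(math.log(2.0), rel=1e-6)

    def test_weights_scale_terms_linearly(self, rng):
        labels = self._labels(rng)
        logits = nn.Tensor(rng.normal(size=(2, 3, 8, 8)).astype(np.float32))
        combo = combined_loss(logits, labels, LossWeights(0.5, 0.5)).item()
        parts = 0.5 * soft_dice_loss(logits, labels).item() \
            + 0.5 * cross_entropy_loss(logits, labels).item()
        assert combo == pytest.approx(parts, rel=1e-6)

    def test_out_of_range_label_rejected(self):
        logits = nn.Tensor(np.zeros((1, 2, 2, 2), dtype=np.float32))
        with pytest.raises(ValueError, match="label"):
            combined_loss(logits, np.array([[[0, 2], [0, 0]]]),
                          LossWeights())

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(0.0, 0.0)
        with pytest.raises(ValueError):
            LossWeights(-0.1, 0.5)


# ---------------------------------------------------------------------------
# surface metrics
# ---------------------------------------------------------------------------


def _boundary_bruteforce(mask):
    """Literal definition: foreground voxel with a face-adjacent background
    or volume-edge neighbour."""
    pts = []
    d, h, w = mask.shape
    for z in range(d):
        for y in range(h):
            for x in range(w):
                if not mask[z, y, x]:
                    continue
                for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if not (0 <= zz < d and 0 <= yy < h and 0 <= xx < w) \
                            or not mask[zz, yy, xx]:
                        pts.append((z, y, x))
                        break
    return np.array(sorted(pts), dtype=float)


def _directed_oracle(src, dst):
    return np.array([min(np.linalg.norm(p - q) for q in dst) for p in src])


class TestSurfaceExtraction:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_boundary_matches_exhaustive_definition(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((4, 5, 6)) > 0.6
        got = boundary_points(mask, (1.0, 1.0, 1.0))
        ref = _boundary_bruteforce(mask)
        if ref.size == 0:
            assert got.size == 0
        else:
            np.testing.assert_array_equal(
                np.array(sorted(map(tuple, got))), ref)


class TestDistances:
    def test_identical_masks_are_zero(self):
        m = np.zeros((3, 6, 6), bool)
        m[1, 2:5, 2:5] = True
        assert hd95(m, m) == 0.0
        assert asd(m, m) == 0.0
        assert assd(m, m) == 0.0

    def test_single_voxels_three_apart(self):
        x = np.zeros((1, 8, 8), bool)
        y = np.zeros((1, 8, 8), bool)
        x[0, 2, 2] = True
        y[0, 2, 5] = True
        assert hd95(x, y) == pytest.approx(3.0)
        assert asd(x, y) == pytest.approx(3.0)
        assert assd(x, y) == pytest.approx(3.0)

    def test_offset_squares_match_bruteforce_oracle(self):
        x = np.zeros((1, 16, 16), bool)
        y = np.zeros((1, 16, 16), bool)
        x[0, 2:12, 2:12] = True
        y[0, 4:14, 2:12] = True          # shifted by (2, 0)
        sx = boundary_points(x, (1.0, 1.0, 1.0))
        sy = boundary_points(y, (1.0, 1.0, 1.0))
        pooled = np.concatenate([_directed_oracle(sx, sy),
                                 _directed_oracle(sy, sx)])
        expect_hd = float(np.percentile(pooled, 95))
        expect_asd = float(_directed_oracle(sx, sy).mean())
        assert hd95(x, y) == pytest.approx(expect_hd, abs=1e-9)
        assert asd(x, y) == pytest.approx(expect_asd, abs=1e-9)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_random_small_masks_match_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((3, 5, 5)) > 0.6
        y = rng.random((3, 5, 5)) > 0.6
        if not x.any() or not y.any():
            return
        sx = boundary_points(x, (1.0, 1.0, 1.0))
        sy = boundary_points(y, (1.0, 1.0, 1.0))
        assert len(sx) <= 50 and len(sy) <= 50
        dxy = _directed_oracle(sx, sy)
        dyx = _directed_oracle(sy, sx)
        assert asd(x, y) == pytest.approx(dxy.mean(), abs=1e-9)
        assert assd(x, y) == pytest.approx(0.5 * (dxy.mean() + dyx.mean()),
                                           abs=1e-9)
        pooled = np.concatenate([dxy, dyx])
        assert hd95(x, y) == pytest.approx(np.percentile(pooled, 95),
                                           abs=1e-9)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_assd_symmetric_and_hd100_bounds_asd(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((3, 6, 6)) > 0.5
        y = rng.random((3, 6, 6)) > 0.5
        if not x.any() or not y.any():
            return
        assert assd(x, y) == pytest.approx(assd(y, x), abs=1e-12)
        sx = boundary_points(x, (1.0, 1.0, 1.0))
        sy = boundary_points(y, (1.0, 1.0, 1.0))
        directed = _directed_oracle(sx, sy)
        assert directed.max() >= directed.mean() - 1e-12

    @pytest.mark.parametrize("scale", [0.5, 2.0, 3.7])
    def test_isotropic_spacing_scales_distances_linearly(self, scale):
        rng = np.random.default_rng(5)
        x = rng.random((3, 6, 6)) > 0.55
        y = rng.random((3, 6, 6)) > 0.55
        base_sp = (1.0, 1.0, 1.0)
        scaled = tuple(scale * s for s in base_sp)
        for metric in (hd95, asd, assd):
            assert metric(x, y, scaled) == \
                pytest.approx(scale * metric(x, y, base_sp), rel=1e-9)

    def test_both_empty_is_zero_one_empty_is_flagged_worst_case(self, caplog):
        e = np.zeros((2, 4, 4), bool)
        f = np.zeros((2, 4, 4), bool)
        f[1, 1, 1] = True
        assert hd95(e, e) == 0.0
        with caplog.at_level("WARNING", logger="hybridseg"):
            worst = hd95(e, f)
        diag = math.sqrt(2 ** 2 + 4 ** 2 + 4 ** 2)
        assert worst == pytest.approx(diag)
        assert any("empty" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# confusion matrix and per-case report
# ---------------------------------------------------------------------------


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self, rng):
        truth = rng.integers(0, 4, size=(6, 6))
        cm = confusion_matrix(truth, truth, 4)
        assert (cm == np.diag(np.diag(cm))).all()

    def test_total_count_conserved_and_rows_match_truth(self, rng):
        truth = rng.integers(0, 3, size=(8, 8))
        pred = rng.integers(0, 3, size=(8, 8))
        cm = confusion_matrix(pred, truth, 3)
        assert cm.sum() == truth.size
        for t in range(3):
            assert cm[t].sum() == (truth == t).sum()

    def test_four_pixel_toy(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.array([0, 1, 1, 1])
        np.testing.assert_array_equal(confusion_matrix(pred, truth, 2),
                                      [[1, 1], [0, 2]])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix(np.array([0, 5]), np.array([0, 1]), 2)


class TestEvaluateCase:
    def test_perfect_case(self):
        vol = np.zeros((2, 8, 8), np.int16)
        vol[:, 2:5, 2:5] = 1
        vol[:, 6:8, 6:8] = 2
        rep = evaluate_case(vol, vol, (1.0, 1.0, 1.0), 3)
        assert rep.mean_dsc == 100.0
        assert rep.mean_hd95 == 0.0
        assert rep.mean_assd == 0.0

    def test_absent_in_both_scores_perfect(self):
        vol = np.zeros((2, 6, 6), np.int16)
        vol[:, 1:3, 1:3] = 1
        rep = evaluate_case(vol, vol, (1.0, 1.0, 1.0), num_classes=4)
        assert rep.dsc[3] == 100.0
        assert rep.hd95[3] == 0.0

    def test_absent_in_one_scores_zero_and_is_excluded(self, caplog):
        truth = np.zeros((2, 6, 6), np.int16)
        truth[:, 1:3, 1:3] = 1
        pred = np.zeros_like(truth)
        with caplog.at_level("WARNING", logger="hybridseg"):
            rep = evaluate_case(pred, truth, (1.0, 1.0, 1.0), 2)
        assert rep.dsc[1] == 0.0
        assert np.isnan(rep.hd95[1])
        assert rep.skipped_classes == [1]

    def test_confusion_row_sums_equal_truth_counts(self, rng):
        truth = rng.integers(0, 3, size=(2, 6, 6))
        pred = rng.integers(0, 3, size=(2, 6, 6))
        rep = evaluate_case(pred, truth, (1.0, 1.0, 1.0), 3)
        for t in range(3):
            assert rep.confusion[t].sum() == (truth == t).sum()
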