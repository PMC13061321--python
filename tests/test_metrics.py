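"""Metric oracles: mIoU/Dice vs brute force, greedy picking, diversity."""

import numpy as np
import pytest

from mvtomo.metrics import (cos_sim, dice, extract_centers, fds,
                            match_particles, miou)
from mvtomo.synthetic import Particle


def brute_miou(pred, gt):
    classes = sorted(set(np.unique(pred)) | set(np.unique(gt)))
    vals = []
    for c in classes:
        inter = np.sum((pred == c) & (gt == c))
        union = np.sum((pred == c) | (gt == c))
        vals.append(inter / union)
    return float(np.mean(vals))


def brute_dice(pred, gt):
    classes = sorted(set(np.unique(pred)) | set(np.unique(gt)))
    vals = []
    for c in classes:
        inter = np.sum((pred == c) & (gt == c))
        vals.append(2 * inter / (np.sum(pred == c) + np.sum(gt == c)))
    return float(np.mean(vals))


class TestOverlapScores:
    def test_identity(self, rng):
        x = rng.integers(0, 3, size=(6, 6, 6))
        assert miou(x, x) == pytest.approx(1.0)
        assert dice(x, x) == pytest.approx(1.0)

    def test_hand_counted_miou(self):
        gt = np.zeros((2, 2, 2), dtype=np.int64)
        gt[0] = 1  # 4 foreground voxels
        pred = np.zeros((2, 2, 2), dtype=np.int64)
        # IoU_bg = 4/8, IoU_fg = 0 -> mean 0.25
        assert miou(pred, gt) == pytest.approx(0.25)

    def test_dice_closed_form(self):
        gt = np.zeros((8,), dtype=np.int64).reshape(2, 2, 2)
        pred = gt.copy()
        gt.ravel()[:4] = 1
        pred.ravel()[2:6] = 1  # |pred|=4, |gt|=4, overlap 2
        c_fg = 2 * 2 / (4 + 4)
        c_bg = 2 * 2 / (4 + 4)
        assert dice(pred, gt) == pytest.approx((c_fg + c_bg) / 2) == 0.5

    def test_disjoint_equal_masks(self):
        gt = np.zeros((2, 2, 2), dtype=np.int64)
        pred = np.zeros((2, 2, 2), dtype=np.int64)
        gt.ravel()[:4] = 1
        pred.ravel()[4:] = 1
        # both classes fully disjoint between pred and gt
        assert dice(pred, gt) == pytest.approx(0.0)

    def test_matches_brute_force_random(self, rng):
        for _ in range(1000):
            shape = tuple(rng.integers(2, 5, size=3))
            n_cls = int(rng.integers(2, 5))
            pred = rng.integers(0, n_cls, size=shape)
            gt = rng.integers(0, n_cls, size=shape)
            assert miou(pred, gt) == pytest.approx(brute_miou(pred, gt))
            assert dice(pred, gt) == pytest.approx(brute_dice(pred, gt))

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            pred = rng.integers(0, 3, size=(4, 4, 4))
            gt = rng.integers(0, 3, size=(4, 4, 4))
            m, d = miou(pred, gt), dice(pred, gt)
            assert 0.0 <= m <= 1.0 and 0.0 <= d <= 1.0
            assert m == pytest.approx(miou(gt, pred))
            assert d == pytest.approx(dice(gt, pred))
            assert d >= m - 1e-12  # 2u/(a+b) >= u/(a+b-u) per class

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            miou(rng.integers(0, 2, size=(2, 2, 2)),
                 rng.integers(0, 2, size=(3, 3, 3)))


class TestExtractCenters:
    def test_single_cube_blob(self):
        lab = np.zeros((16, 16, 16), dtype=np.int64)
        lab[6:11, 6:11, 6:11] = 3
        recs = extract_centers(lab)
        assert len(recs) == 1
        assert recs[0].class_id == 3
        assert recs[0].center == (8.0, 8.0, 8.0)

    def test_two_blobs_same_class(self):
        lab = np.zeros((16, 16, 16), dtype=np.int64)
        lab[1:4, 1:4, 1:4] = 2
        lab[10:13, 10:13, 10:13] = 2
        assert len(extract_centers(lab)) == 2

    def test_min_size_drops_specks(self):
        lab = np.zeros((8, 8, 8), dtype=np.int64)
        lab[0, 0, 0] = 1          # 1-voxel speck
        lab[4:7, 4:7, 4:7] = 1    # 27-voxel blob
        recs = extract_centers(lab, min_size=5)
        assert len(recs) == 1
        assert recs[0].center == (5.0, 5.0, 5.0)


class TestMatchParticles:
    def test_exact_center_match(self):
        gt = [Particle(1, (5, 5, 5), 5.0)]
        pred = [Particle(1, (5, 5, 5), 0.0)]
        res = match_particles(pred, gt)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_distance_equal_radius_is_not_a_match(self):
        gt = [Particle(1, (0, 0, 0), 4.0)]
        pred = [Particle(1, (4, 0, 0), 0.0)]
        res = match_particles(pred, gt)
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    def test_two_predictions_one_target(self):
        gt = [Particle(1, (0, 0, 0), 5.0)]
        pred = [Particle(1, (1, 0, 0), 0.0), Particle(1, (0, 2, 0), 0.0)]
        res = match_particles(pred, gt)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)
        assert res.precision == pytest.approx(0.5)
        assert res.recall == pytest.approx(1.0)
        assert res.f1 == pytest.approx(2 / 3)

    def test_class_aware(self):
        gt = [Particle(1, (0, 0, 0), 5.0)]
        pred = [Particle(2, (0, 0, 0), 0.0)]
        res = match_particles(pred, gt)
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    def test_greedy_prefers_closest(self):
        gt = [Particle(1, (0, 0, 0), 5.0), Particle(1, (6, 0, 0), 5.0)]
        pred = [Particle(1, (2, 0, 0), 0.0)]
        res = match_particles(pred, gt)
        assert res.matches[0][1] == 0  # matched to nearer target
        assert (res.tp, res.fn) == (1, 1)

    def test_counts_conserved_random(self, rng):
        for _ in range(200):
            gt = [Particle(int(rng.integers(1, 3)),
                           tuple(rng.uniform(0, 20, 3)), float(rng.uniform(1, 4)))
                  for _ in range(rng.integers(0, 6))]
            pred = [Particle(int(rng.integers(1, 3)),
                             tuple(rng.uniform(0, 20, 3)), 0.0)
                    for _ in range(rng.integers(0, 6))]
            res = match_particles(pred, gt)
            assert res.tp + res.fn == len(gt)
            assert res.tp + res.fp == len(pred)

    def test_negative_radius(self):
        with pytest.raises(ValueError):
            match_particles([], [Particle(1, (0, 0, 0), -1.0)])

    def test_empty_conventions(self):
        res = match_particles([], [])
        assert res.precision == 0.0 and res.recall == 0.0 and res.f1 == 0.0


class TestFeatureDiversity:
    def test_cos_sim_identical(self, rng):
        v = rng.normal(size=16)
        assert cos_sim(v, v) == pytest.approx(1.0)

    def test_cos_sim_orthogonal(self):
        assert cos_sim([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_cos_sim_closed_form(self):
        assert cos_sim([1, 0], [1, 1]) == pytest.approx(1 / np.sqrt(2))

    def test_cos_sim_zero_norm(self):
        with pytest.raises(ValueError):
            cos_sim([0, 0], [1, 1])

    def test_fds_identical_zero(self, rng):
        f = rng.normal(size=(5, 8))
        assert fds(f, f) == pytest.approx(0.0)

    def test_fds_mean_of_squared_distances(self):
        f1 = np.array([[0.0, 0.0], [0.0, 0.0]])
        f2 = np.array([[1.0, 0.0], [1.0, np.sqrt(2)]])
        # per-pair squared distances 1 and 3 -> mean 2
        assert fds(f1, f2) == pytest.approx(2.0)

    def test_fds_quadratic_scaling(self, rng):
        f1 = rng.normal(size=(4, 6))
        f2 = rng.normal(size=(4, 6))
        assert fds(3 * f1, 3 * f2) == pytest.approx(9 * fds(f1, f2))
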