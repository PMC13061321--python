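"""Masked-view planning, reconstruction decoder, reconstruction loss."""

import numpy as np
import pytest

from mvtomo.autodiff import Tensor
from mvtomo.model import ALL_VIEWS, ModelConfig, MultiViewSegmenter
from mvtomo.multiview import View
from mvtomo.vsl import MaskPlan, apply_mask, plan_mask, recon_loss


class TestPlanMask:
    def test_half_rate_512(self):
        plan = plan_mask(512, 0.5, seed=3)
        assert plan.n_masked == 256
        assert len(set(plan.masked_indices.tolist())) == 256
        assert plan.masked_indices.max() < 512

    def test_rounding_floor_case(self):
        plan = plan_mask(512, 0.002, seed=0)
        assert plan.n_masked == 1

    def test_deterministic(self):
        a = plan_mask(64, 0.5, seed=9)
        b = plan_mask(64, 0.5, seed=9)
        assert a.masked_view == b.masked_view
        np.testing.assert_array_equal(a.masked_indices, b.masked_indices)

    def test_view_choice_varies_with_seed(self):
        views = {plan_mask(64, 0.5, seed=s).masked_view for s in range(30)}
        assert views == set(View)

    @pytest.mark.parametrize("eta", [0.0, 1.0, -0.1, 1.5])
    def test_rate_bounds(self, eta):
        with pytest.raises(ValueError):
            plan_mask(64, eta, seed=0)


class TestApplyMask:
    def test_masked_rows_replaced_visible_untouched(self, rng):
        tokens = Tensor(rng.normal(size=(2, 8, 4)).astype(np.float32))
        plan = MaskPlan(View.XY, np.array([1, 5]), 0.25)
        mask_tok = Tensor(rng.normal(size=4).astype(np.float32))
        pos = Tensor(rng.normal(size=(8, 4)).astype(np.float32))
        out = apply_mask(tokens, plan, mask_tok, pos)
        visible = [i for i in range(8) if i not in (1, 5)]
        np.testing.assert_allclose(out.data[:, visible], tokens.data[:, visible],
                                   atol=1e-6)
        for i in (1, 5):
            np.testing.assert_allclose(out.data[0, i], mask_tok.data + pos.data[i],
                                       atol=1e-6)


class TestReconstruct:
    def model(self):
        return MultiViewSegmenter(ModelConfig.toy(init_seed=2))

    def test_output_shape_contract(self, rng):
        m = self.model()
        x = rng.normal(size=(3, 16, 16, 16)).astype(np.float32)
        loss, rec, plan = m.reconstruct(x, seed=5)
        assert rec.data.shape == (3, plan.n_masked, 64)  # 4^3 voxel patches
        assert plan.n_masked == 32  # eta=0.5 of L=64

    def test_empty_mask_degenerate(self, rng):
        m = self.model()
        dec = m.recon
        feats = {v: Tensor(rng.normal(size=(2, 8, 32)).astype(np.float32))
                 for v in ALL_VIEWS}
        plan = MaskPlan(View.XY, np.array([], dtype=int), 0.01)
        out = dec(feats, plan, ALL_VIEWS)
        assert out.data.shape[1] == 0
        loss = recon_loss(out, np.zeros((2, 8, 64)), plan)
        assert float(loss.data) == 0.0

    def test_unmasked_views_enter_unmodified(self, rng):
        """Supplying the segmentation pass's features for the unmasked
        views is exactly equivalent to recomputing them."""
        m = self.model()
        x = rng.normal(size=(2, 16, 16, 16)).astype(np.float32)
        loss_a, rec_a, plan_a = m.reconstruct(x, seed=11)
        out = m.segment(x)
        reuse = {v: f[-1] for v, f in out.layer_feats.items()}
        loss_b, rec_b, plan_b = m.reconstruct(x, seed=11, reuse_feats=reuse,
                                              nodes=out.nodes)
        assert plan_a.masked_view == plan_b.masked_view
        np.testing.assert_allclose(rec_a.data, rec_b.data, atol=1e-5)


class TestReconLoss:
    def test_perfect_reconstruction_zero(self, rng):
        target = rng.normal(size=(2, 8, 64)).astype(np.float32)
        plan = MaskPlan(View.XY, np.arange(3), 0.5)
        loss = recon_loss(Tensor(target[:, :3]), target, plan)
        assert float(loss.data) == 0.0

    def test_unit_offset_gives_one(self, rng):
        target = rng.normal(size=(1, 8, 64)).astype(np.float32)
        plan = MaskPlan(View.XY, np.arange(4), 0.5)
        loss = recon_loss(Tensor(target[:, :4] + 1.0), target, plan)
        assert float(loss.data) == pytest.approx(1.0, abs=1e-5)

    def test_matches_brute_force_mean(self, rng):
        target = rng.normal(size=(2, 10, 16)).astype(np.float32)
        rec = rng.normal(size=(2, 4, 16)).astype(np.float32)
        idx = np.array([0, 3, 7, 9])
        plan = MaskPlan(View.YZ, idx, 0.4)
        loss = recon_loss(Tensor(rec), target, plan)
        brute = np.mean((rec - target[:, idx]) ** 2)
        assert float(loss.data) == pytest.approx(brute, rel=1e-5)

    def test_loss_ignores_visible_positions(self, rng):
        """Perturbing the original volume at visible positions leaves the
        loss unchanged (loss is computed on masked patches only)."""
        target = rng.normal(size=(1, 8, 16)).astype(np.float32)
        rec = rng.normal(size=(1, 3, 16)).astype(np.float32)
        idx = np.array([1, 4, 6])
        plan = MaskPlan(View.XY, idx, 0.4)
        base = float(recon_loss(Tensor(rec), target, plan).data)
        perturbed = target.copy()
        visible = [i for i in range(8) if i not in idx]
        perturbed[:, visible] += 100.0
        assert float(recon_loss(Tensor(rec), perturbed, plan).data) == base

    def test_shape_mismatch(self, rng):
        plan = MaskPlan(View.XY, np.arange(2), 0.25)
        with pytest.raises(ValueError, match="match"):
            recon_loss(Tensor(np.zeros((1, 3, 16))), np.zeros((1, 8, 16)), plan)


def test_recon_decoder_learns_constant_volumes(rng):
    """Short reconstruction-only training on constant-intensity volumes
    beats a mean-over-everything baseline on the masked patches."""
    from mvtomo.training import TrainConfig, pretrain

    cfg = TrainConfig(model=ModelConfig.toy(init_seed=0), batch_size=8,
                      n_steps=60, seed=0)
    rng2 = np.random.default_rng(0)
    vols = [np.full((16, 16, 16), c, dtype=np.float32)
            for c in rng2.uniform(-1, 1, size=24)]
    data = [(v, np.zeros((16, 16, 16), dtype=np.int64)) for v in vols]
    model, history = pretrain(data, cfg)
    # held-out constants
    test_vols = np.stack([np.full((16, 16, 16), c, dtype=np.float32)
                          for c in rng2.uniform(-1, 1, size=8)])
    from mvtomo.autodiff import no_grad
    with no_grad():
        loss, rec, plan = model.reconstruct(test_vols, seed=123)
    target = model.raw_patches(test_vols, plan.masked_view)[:, plan.masked_indices]
    model_mse = float(np.mean((rec.data - target) ** 2))
    baseline_mse = float(np.mean((target - np.mean(vols)) ** 2))
    assert model_mse < baseline_mse
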