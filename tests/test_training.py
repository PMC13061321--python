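"""Composite loss closed forms, schedule, training loop, checkpointing."""

import numpy as np
import pytest

from mvtomo.autodiff import Tensor
from mvtomo.model import ModelConfig, MultiViewSegmenter
from mvtomo.multiview import View
from mvtomo.synthetic import simulate_dataset, toy_simulation_config
from mvtomo.training import (TrainConfig, cross_entropy, load_checkpoint, lr_at,
                             predict, save_checkpoint, total_loss,
                             toy_train_config, train)

LN2 = float(np.log(2.0))


def uniform_logits(n_cls=2, shape=(1, 4, 4, 4)):
    return Tensor(np.zeros((shape[0], n_cls) + shape[1:], dtype=np.float32))


class TestLoss:
    def test_uniform_two_class_terms(self, rng):
        """Uniform predictions over 2 classes: each CE term is ln 2, the
        four segmentation terms total 4 ln 2."""
        labels = rng.integers(0, 2, size=(1, 4, 4, 4))
        view_logits = {v: uniform_logits() for v in View}
        loss, terms = total_loss(labels, view_logits, uniform_logits())
        for key in ("ce_XY", "ce_XZ", "ce_YZ", "ce_fused"):
            assert terms[key] == pytest.approx(LN2, abs=1e-6)
        assert float(loss.data) == pytest.approx(4 * LN2, abs=1e-5)

    def test_perfect_prediction_near_zero(self):
        labels = np.zeros((1, 4, 4, 4), dtype=np.int64)
        logits = np.zeros((1, 2, 4, 4, 4), dtype=np.float32)
        logits[:, 0] = 50.0  # huge margin for the correct class
        view_logits = {v: Tensor(logits) for v in View}
        loss, _ = total_loss(labels, view_logits, Tensor(3 * logits))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-6)

    def test_xz_yz_terms_commute(self, rng):
        labels = rng.integers(0, 2, size=(1, 4, 4, 4))
        a = Tensor(rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32))
        b = Tensor(rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32))
        fused = uniform_logits()
        l1, _ = total_loss(labels, {View.XZ: a, View.YZ: b}, fused)
        l2, _ = total_loss(labels, {View.XZ: b, View.YZ: a}, fused)
        # swapping which view carries which field changes realignment,
        # but swapping the *order of terms* must not change the sum
        l3, _ = total_loss(labels, {View.YZ: b, View.XZ: a}, fused)
        assert float(l1.data) == pytest.approx(float(l3.data), rel=1e-6)

    def test_recon_term_additive(self, rng):
        labels = rng.integers(0, 2, size=(1, 4, 4, 4))
        view_logits = {v: uniform_logits() for v in View}
        base, _ = total_loss(labels, view_logits, uniform_logits(), recon=0.0)
        with_recon, terms = total_loss(labels, view_logits, uniform_logits(),
                                       recon=Tensor(0.25))
        assert float(with_recon.data) - float(base.data) == pytest.approx(0.25, abs=1e-6)
        assert terms["recon"] == pytest.approx(0.25)

    def test_all_views_equal_gives_four_times_single(self, rng):
        """With a spatially constant score field (realignment-invariant)
        shared by every view and the fusion, the composite loss is four
        times the single-view cross-entropy."""
        labels = rng.integers(0, 2, size=(1, 4, 4, 4))
        per_class = rng.normal(size=2).astype(np.float32)
        logits = Tensor(np.broadcast_to(per_class.reshape(1, 2, 1, 1, 1),
                                        (1, 2, 4, 4, 4)).copy())
        single = float(cross_entropy(logits, labels).data)
        loss, _ = total_loss(labels, {v: logits for v in View}, logits)
        assert float(loss.data) == pytest.approx(4 * single, rel=1e-5)

    def test_class_mismatch_rejected(self, rng):
        labels = np.full((1, 4, 4, 4), 5, dtype=np.int64)
        with pytest.raises(ValueError, match="out of range"):
            cross_entropy(uniform_logits(), labels)


class TestSchedule:
    def test_decay_steps(self):
        cfg = TrainConfig()
        assert lr_at(0, cfg) == pytest.approx(1e-3)
        assert lr_at(99, cfg) == pytest.approx(1e-3)
        assert lr_at(100, cfg) == pytest.approx(1e-4)
        assert lr_at(200, cfg) == pytest.approx(1e-5)
        assert lr_at(250, cfg) == pytest.approx(1e-5)

    def test_negative_epoch(self):
        with pytest.raises(ValueError):
            lr_at(-1, TrainConfig())


def tiny_dataset(n=12, seed=3):
    return simulate_dataset(toy_simulation_config(seed=seed), n, seed=seed)


class TestTrainLoop:
    def test_zero_lr_leaves_parameters_unchanged(self):
        """A gradient step with lr=0 is the optimizer identity; only the
        decoder-head bias differs, set once to the label log-priors before
        the first step."""
        data = tiny_dataset()
        cfg = toy_train_config(seed=0)
        cfg.n_steps, cfg.lr, cfg.ema_decay = 1, 0.0, 0.0
        ref = MultiViewSegmenter(cfg.model)
        before = {k: v.copy() for k, v in ref.state_dict().items()
                  if k.startswith("param.")}
        model, _ = train(data, cfg)
        after = model.state_dict()
        for k, v in before.items():
            if k == "param.decoder.head.bias":
                continue
            np.testing.assert_array_equal(after[k], v)
        labs = np.concatenate([item[1].labels.ravel() for item in data])
        counts = np.bincount(labs, minlength=2).astype(float)
        priors = (counts + 1.0) / (counts.sum() + 2)
        np.testing.assert_allclose(after["param.decoder.head.bias"],
                                   np.log(priors), rtol=1e-5)

    def test_loss_decreases_on_toy_data(self):
        data = tiny_dataset(n=16)
        cfg = toy_train_config(seed=0)
        cfg.n_steps = 25
        model, history = train(data, cfg)
        losses = history["loss"]
        assert np.mean(losses[-5:]) < np.mean(losses[:5])

    def test_vsl_disabled_contributes_zero(self):
        data = tiny_dataset()
        cfg = toy_train_config(seed=0, use_vsl=False)
        cfg.n_steps = 2
        _, history = train(data, cfg)
        assert all(t["recon"] == 0.0 for t in history["terms"])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], toy_train_config(seed=0))

    def test_per_epoch_checkpoints(self, tmp_path):
        data = tiny_dataset(n=8)
        cfg = toy_train_config(seed=0, use_vsl=False)
        cfg.n_steps = 2  # batch 8 on 8 patches: one step per epoch
        train(data, cfg, checkpoint_dir=tmp_path / "ck")
        names = sorted(p.name for p in (tmp_path / "ck").glob("*.npz"))
        assert names == ["epoch_0001.npz", "epoch_0002.npz"]


class TestPredict:
    def test_single_tile_shapes(self, rng):
        model = MultiViewSegmenter(ModelConfig.toy(init_seed=1))
        scores, labels = predict(rng.normal(size=(16, 16, 16)).astype(np.float32),
                                 model)
        assert scores.shape == (16, 16, 16, 2)
        assert labels.shape == (16, 16, 16)
        np.testing.assert_allclose(scores.sum(axis=-1), 1.0, atol=1e-4)

    def test_overlap_tiling_count_and_crop(self, rng):
        model = MultiViewSegmenter(ModelConfig.toy(init_seed=1))
        vol = rng.normal(size=(32, 32, 32)).astype(np.float32)
        scores, labels = predict(vol, model, overlap=0.5)
        assert scores.shape == (32, 32, 32, 2)  # 27 tiles at stride 8, fused

    def test_small_volume_padded(self, rng):
        model = MultiViewSegmenter(ModelConfig.toy(init_seed=1))
        scores, labels = predict(rng.normal(size=(10, 12, 16)).astype(np.float32),
                                 model)
        assert labels.shape == (10, 12, 16)

    def test_checkpoint_round_trip_bitwise(self, rng, tmp_path):
        data = tiny_dataset()
        cfg = toy_train_config(seed=0)
        cfg.n_steps = 2
        model, _ = train(data, cfg)
        vol = rng.normal(size=(16, 16, 16)).astype(np.float32)
        scores_a, _ = predict(vol, model)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model)
        loaded = load_checkpoint(path)
        scores_b, _ = predict(vol, loaded)
        np.testing.assert_array_equal(scores_a, scores_b)

    def test_checkpoint_config_mismatch(self, tmp_path):
        model = MultiViewSegmenter(ModelConfig.toy(init_seed=0))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model)
        other = MultiViewSegmenter(ModelConfig.toy(init_seed=0, channels=64, heads=8))
        import numpy as _np
        with _np.load(path) as data:
            state = {k: data[k] for k in data.files if k != "__config__"}
        with pytest.raises(ValueError, match="mismatch"):
            other.load_state_dict(state)
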