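"""Composite objective, optimization schedule, training loop, inference.

The training objective sums voxel-mean cross-entropy over the three
per-view predictions (realigned to the canonical grid), the fused
prediction, and — when view-masked self-supervision is enabled — the
masked-patch reconstruction MSE, all with unit weights.  Adam with a step
schedule that multiplies the learning rate by 0.1 every 100 epochs
("decayed 90 %").

Inference tiles arbitrary volumes into model-sized patches at 50 %
overlap, predicts per-class probabilities per tile and blends them with
the raised-cosine window of :mod:`mvtomo.io_volumes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor, cross_entropy_onehot, no_grad
from .io_volumes import LabelVolume, Volume, fuse_tiles, make_window, tile
from .model import ModelConfig, MultiViewSegmenter
from .multiview import View, realign_spatial

__all__ = ["TrainConfig", "cross_entropy", "total_loss", "lr_at", "train",
           "predict", "save_checkpoint", "load_checkpoint", "toy_train_config"]


@dataclass
class TrainConfig:
    """Optimization settings; model hyperparameters live in ``model``."""

    model: ModelConfig = field(default_factory=ModelConfig)
    epochs: int = 200
    batch_size: int = 72
    lr: float = 1e-3
    decay_factor: float = 0.1     # "decayed 90%": lr loses 90% of its value
    decay_every: int = 100        # epochs
    seed: int = 0
    n_steps: int | None = None    # when set, run exactly this many steps
    ema_decay: float = 0.99       # Polyak parameter averaging (0 disables)
    clip_norm: float = 5.0        # global gradient-norm clip (0 disables)
    val_fraction: float = 0.0


def toy_train_config(seed: int = 0, **model_overrides) -> TrainConfig:
    """Desk-scale profile: toy model, 300 optimizer steps, batch 8."""
    return TrainConfig(model=ModelConfig.toy(init_seed=seed, **model_overrides),
                       batch_size=8, n_steps=300, seed=seed)


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Stepwise-decayed learning rate at a given epoch."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.lr * cfg.decay_factor ** (epoch // cfg.decay_every)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Voxel-mean cross-entropy.

    ``logits`` is (B, N+1, H, W, D); ``labels`` integer (B, H, W, D)."""
    labels = np.asarray(labels)
    n_cls = logits.data.shape[1]
    if labels.max(initial=0) >= n_cls:
        raise ValueError(
            f"label {labels.max()} out of range for {n_cls} classes"
        )
    if labels.shape != logits.data.shape[:1] + logits.data.shape[2:]:
        raise ValueError(
            f"labels shape {labels.shape} incompatible with logits {logits.data.shape}"
        )
    onehot = np.zeros(logits.data.shape, dtype=np.float32)
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
    return cross_entropy_onehot(logits, onehot, axis=1)


def realign_logits(logits: Tensor, view) -> Tensor:
    """Bring (B, N+1, h, w, d) view-frame logits back to the canonical grid."""
    perm = realign_spatial(View(view))
    return logits.transpose((0, 1) + tuple(a + 2 for a in perm))


def total_loss(labels: np.ndarray, view_logits: dict, fused: Tensor,
               recon: Tensor | float = 0.0) -> tuple[Tensor, dict]:
    """CE per realigned view + CE on the fusion + reconstruction term."""
    terms = {}
    loss = None
    for view, logits in view_logits.items():
        term = cross_entropy(realign_logits(logits, view), labels)
        terms[f"ce_{View(view).value}"] = float(term.data)
        loss = term if loss is None else loss + term
    fused_term = cross_entropy(fused, labels)
    terms["ce_fused"] = float(fused_term.data)
    loss = fused_term if loss is None else loss + fused_term
    if isinstance(recon, Tensor):
        terms["recon"] = float(recon.data)
        loss = loss + recon
    else:
        terms["recon"] = float(recon)
        loss = loss + float(recon)
    return loss, terms


def _init_head_prior(model: MultiViewSegmenter, labels: np.ndarray) -> None:
    """Initialize the decoder head bias to the log class priors of the
    training labels, so early optimization is not spent learning the
    (heavily background-skewed) marginal class distribution."""
    n_cls = model.cfg.n_classes + 1
    counts = np.bincount(labels.reshape(-1), minlength=n_cls).astype(np.float64)
    priors = (counts + 1.0) / (counts.sum() + n_cls)
    head = model.decoder.head if hasattr(model.decoder, "head") else model.decoder.fuse2
    if head.bias is not None:
        head.bias.data = np.log(priors).astype(np.float32)


def recalibrate_batchnorm(model: MultiViewSegmenter, volumes: np.ndarray,
                          chunk: int = 40) -> None:
    """Re-estimate batch-norm statistics with full forward passes.

    Running averages accumulated from small noisy minibatches are a poor
    estimate of the activation statistics; averaging the moments over a
    few large chunks of the training set removes that mismatch."""
    from . import nn as _nn

    collected: dict[int, list] = {}
    orig_forward = _nn.BatchNorm3d.forward

    def collecting(self, x):
        mu = x.data.mean(axis=(0, 2, 3, 4))
        var = x.data.var(axis=(0, 2, 3, 4))
        collected.setdefault(id(self), []).append((mu, var))
        return orig_forward(self, x)

    was_training = model.training
    model.train()
    _nn.BatchNorm3d.forward = collecting
    try:
        with no_grad():
            for i in range(0, len(volumes), chunk):
                model.segment(volumes[i : i + chunk])
    finally:
        _nn.BatchNorm3d.forward = orig_forward
        model.train(was_training)
    for _, mod in model._named_modules():
        stats = collected.get(id(mod))
        if stats and "running_mean" in getattr(mod, "_buffers", {}):
            mod._buffers["running_mean"] = np.mean([s[0] for s in stats], axis=0).astype(np.float32)
            mod._buffers["running_var"] = np.mean([s[1] for s in stats], axis=0).astype(np.float32)


def _clip_gradients(params, max_norm: float) -> None:
    if not max_norm:
        return
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in params
                        if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def _check_finite(terms: dict, step: int):
    for name, value in terms.items():
        if not np.isfinite(value):
            raise FloatingPointError(
                f"non-finite loss term '{name}' ({value}) at step {step}"
            )


def train(dataset, cfg: TrainConfig, eval_fn=None, log=None,
          checkpoint_dir=None):
    """Train a model on (Volume, LabelVolume) pairs.

    ``dataset`` is a sequence of ``(Volume | ndarray, LabelVolume)`` (extra
    tuple entries such as particle lists are ignored).  Returns
    ``(model, history)`` where history records per-step losses and any
    ``eval_fn(model) -> dict`` results per epoch.  With ``checkpoint_dir``
    set, a checkpoint is written at every epoch boundary.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    vols = np.stack([
        np.asarray(item[0].data if isinstance(item[0], Volume) else item[0],
                   dtype=np.float32)
        for item in dataset
    ])
    labs = np.stack([
        np.asarray(item[1].labels if isinstance(item[1], LabelVolume) else item[1])
        for item in dataset
    ])
    model = MultiViewSegmenter(cfg.model)
    model.train()
    _init_head_prior(model, labs)
    params = model.parameters()
    # bias-corrected Polyak average of the weights, evaluated at the end
    ema = [np.zeros_like(p.data) for p in params]
    ema_decay = cfg.ema_decay
    opt = nn.Adam(params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    n = len(dataset)
    steps_per_epoch = max(1, n // cfg.batch_size)
    n_steps = cfg.n_steps if cfg.n_steps is not None else cfg.epochs * steps_per_epoch
    history = {"loss": [], "terms": [], "eval": []}
    for step in range(n_steps):
        epoch = step // steps_per_epoch
        opt.lr = lr_at(epoch, cfg)
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        xb, yb = vols[idx], labs[idx]
        out = model.segment(xb, kmeans_seed=step)
        recon: Tensor | float = 0.0
        if cfg.model.use_vsl:
            reuse = {v: feats[-1] for v, feats in out.layer_feats.items()}
            recon, _, _ = model.reconstruct(xb, seed=cfg.seed * 100003 + step,
                                            kmeans_seed=step, reuse_feats=reuse,
                                            nodes=out.nodes)
        loss, terms = total_loss(yb, out.view_logits, out.fused, recon)
        _check_finite(terms, step)
        opt.zero_grad()
        loss.backward()
        _clip_gradients(params, cfg.clip_norm)
        opt.step()
        if ema_decay:
            for e, p in zip(ema, params):
                e *= ema_decay
                e += (1.0 - ema_decay) * p.data
        history["loss"].append(float(loss.data))
        history["terms"].append(terms)
        if log is not None and (step % 20 == 0 or step == n_steps - 1):
            log(f"step {step + 1}/{n_steps} loss {float(loss.data):.4f}")
        if (step + 1) % steps_per_epoch == 0:
            if checkpoint_dir is not None:
                from pathlib import Path

                ckdir = Path(checkpoint_dir)
                ckdir.mkdir(parents=True, exist_ok=True)
                save_checkpoint(ckdir / f"epoch_{epoch + 1:04d}.npz", model)
            if eval_fn is not None:
                model.eval()
                with no_grad():
                    history["eval"].append({"step": step + 1, **eval_fn(model)})
                model.train()
    if ema_decay:
        correction = 1.0 - ema_decay ** n_steps
        for e, p in zip(ema, params):
            p.data = (e / correction).astype(np.float32)
    recalibrate_batchnorm(model, vols)
    model.eval()
    return model, history


def pretrain(dataset, cfg: TrainConfig, log=None):
    """Reconstruction-only training (self-supervised phase)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    vols = np.stack([
        np.asarray(item[0].data if isinstance(item[0], Volume) else item[0],
                   dtype=np.float32)
        for item in dataset
    ])
    model = MultiViewSegmenter(cfg.model)
    model.train()
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    n = len(vols)
    steps_per_epoch = max(1, n // cfg.batch_size)
    n_steps = cfg.n_steps if cfg.n_steps is not None else cfg.epochs * steps_per_epoch
    history = {"loss": []}
    for step in range(n_steps):
        opt.lr = lr_at(step // steps_per_epoch, cfg)
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        loss, _, _ = model.reconstruct(vols[idx], seed=cfg.seed * 100003 + step,
                                       kmeans_seed=step)
        if not np.isfinite(float(loss.data)):
            raise FloatingPointError(f"non-finite loss term 'recon' at step {step}")
        opt.zero_grad()
        loss.backward()
        _clip_gradients(model.parameters(), cfg.clip_norm)
        opt.step()
        history["loss"].append(float(loss.data))
        if log is not None and (step % 20 == 0 or step == n_steps - 1):
            log(f"pretrain step {step + 1}/{n_steps} mse {float(loss.data):.5f}")
    model.eval()
    return model, history


def _softmax_np(x: np.ndarray, axis: int) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def predict(volume, model: MultiViewSegmenter, overlap: float = 0.5,
            per_view: bool = False):
    """Overlap-tile inference on a volume of arbitrary shape.

    Tiles at the model's input size with the given overlap, predicts
    per-class probabilities per tile, blends them with the raised-cosine
    window and takes the voxel-wise argmax.  Returns
    ``(scores, LabelVolume)`` where ``scores`` is (H, W, D, N+1); with
    ``per_view=True`` a third dict maps each view to its own blended
    canonical-frame score field.
    """
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume, dtype=np.float32)
    size = model.cfg.input_size
    pad = tuple(max(0, size - s) for s in data.shape)
    if any(pad):
        data = np.pad(data, [(0, p) for p in pad])
    vol = Volume(data)
    grid_tiles = tile(vol, size, overlap_fraction=overlap)
    window = make_window(size)
    model.eval()
    fused_blocks = []
    view_blocks = {v: [] for v in model.cfg.views}
    with no_grad():
        for origin, block in grid_tiles.patches:
            out = model.segment(block[None])
            probs = _softmax_np(out.fused.data[0], axis=0)
            fused_blocks.append((origin, np.moveaxis(probs, 0, -1)))
            if per_view:
                for view in model.cfg.views:
                    aligned = realign_logits(out.view_logits[view], view).data[0]
                    vp = _softmax_np(aligned, axis=0)
                    view_blocks[view].append((origin, np.moveaxis(vp, 0, -1)))
    full_shape = grid_tiles.padded_shape
    scores = fuse_tiles(fused_blocks, window, full_shape)
    orig = volume.data.shape if isinstance(volume, Volume) else np.asarray(volume).shape
    crop = tuple(slice(0, s) for s in orig)
    scores = scores[crop]
    labels = LabelVolume(scores.argmax(axis=-1).astype(np.int64), model.cfg.n_classes)
    if not per_view:
        return scores, labels
    view_scores = {
        v: fuse_tiles(blocks, window, full_shape)[crop]
        for v, blocks in view_blocks.items()
    }
    return scores, labels, view_scores


def save_checkpoint(path, model: MultiViewSegmenter) -> None:
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    state = model.state_dict()
    np.savez(path, __config__=np.frombuffer(model.cfg.to_json().encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> MultiViewSegmenter:
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    with np.load(path) as data:
        cfg = ModelConfig.from_json(bytes(data["__config__"]).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = MultiViewSegmenter(cfg)
    model.load_state_dict(state)
    model.eval()
    return model
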