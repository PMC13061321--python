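"""View-masked self-supervised learning.

Each step masks one randomly chosen view: a fraction eta of that view's
tokens is replaced by a learned mask token plus the view's position
embedding, while the other two views enter unmodified.  A lightweight
transformer decoder attends over the concatenated multi-view encoder
output and regresses the raw flattened voxel contents of the masked
patches; the loss is the mean squared error over masked patches only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, concat, take
from .multiview import View
from .transformer import EncoderConfig, StandardLayer

__all__ = ["MaskPlan", "plan_mask", "apply_mask", "ReconDecoder", "recon_loss"]


@dataclass(frozen=True)
class MaskPlan:
    masked_view: View
    masked_indices: np.ndarray  # sorted token indices within the masked view
    rate: float

    @property
    def n_masked(self) -> int:
        return len(self.masked_indices)


def plan_mask(length: int, eta: float, seed: int,
              views=(View.XY, View.XZ, View.YZ)) -> MaskPlan:
    """Pick one view uniformly and round(eta * L) token indices uniformly
    without replacement; deterministic given the seed."""
    if not 0 < eta < 1:
        raise ValueError(f"mask rate must be in (0, 1), got {eta}")
    rng = np.random.default_rng(seed)
    views = [View(v) for v in views]
    view = views[int(rng.integers(len(views)))]
    n = int(round(eta * length))
    idx = np.sort(rng.choice(length, size=n, replace=False))
    return MaskPlan(view, idx, eta)


def apply_mask(tokens: Tensor, plan: MaskPlan, mask_token: Tensor,
               pos_table: Tensor) -> Tensor:
    """Replace masked token rows with (mask token + position embedding)."""
    length = tokens.data.shape[1]
    if plan.n_masked and plan.masked_indices.max() >= length:
        raise ValueError("mask plan indices exceed the token sequence length")
    m = np.zeros((length, 1), dtype=np.float32)
    m[plan.masked_indices] = 1.0
    mconst = Tensor(m)
    fill = mask_token.reshape(1, -1) + pos_table
    return tokens * (1.0 - mconst) + fill * mconst


class ReconDecoder(nn.Module):
    """Lightweight transformer decoder over the full multi-view token set."""

    def __init__(self, channels: int, heads: int, patch_dim: int,
                 depth: int = 2, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        cfg = EncoderConfig(layers=depth, channels=channels, heads=heads)
        self.layers = [StandardLayer(cfg, rng) for _ in range(depth)]
        self.norm = nn.LayerNorm(channels)
        self.head = nn.Linear(channels, patch_dim, rng=rng)
        self.mask_token = nn.Parameter(rng.normal(0.0, 0.02, size=channels))

    def forward(self, view_feats: dict, plan: MaskPlan, view_order) -> Tensor:
        """Reconstruct masked patch contents.

        ``view_feats`` maps View -> (B, L, C) final encoder features;
        returns (B, n_masked, patch_dim) predictions for the masked view.
        """
        order = [View(v) for v in view_order]
        if plan.masked_view not in order:
            raise ValueError(f"masked view {plan.masked_view} absent from {order}")
        lengths = [view_feats[v].data.shape[1] for v in order]
        x = concat([view_feats[v] for v in order], axis=1)
        for layer in self.layers:
            x = layer(x)
        x = self.head(self.norm(x))
        offset = sum(lengths[: order.index(plan.masked_view)])
        if plan.n_masked == 0:
            b = x.data.shape[0]
            return Tensor(np.zeros((b, 0, x.data.shape[-1]), dtype=np.float32))
        return take(x, plan.masked_indices + offset, axis=1)


def recon_loss(reconstructed: Tensor, raw_patches: np.ndarray,
               plan: MaskPlan) -> Tensor:
    """MSE over masked patches only.

    ``raw_patches`` is the masked view's full (B, L, patch_dim) raw patch
    array; targets are gathered at the plan's masked indices.
    """
    target = np.asarray(raw_patches, dtype=np.float32)[:, plan.masked_indices, :]
    if reconstructed.data.shape != target.shape:
        raise ValueError(
            f"reconstruction shape {reconstructed.data.shape} does not match "
            f"masked targets {target.shape}"
        )
    if target.size == 0:
        return Tensor(0.0)
    diff = reconstructed - Tensor(target)
    return (diff * diff).mean()
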