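"""Segmentation heads and cross-view logit fusion.

Two interchangeable decoders map encoder token features (on the
H/Hp x W/Wp x D/Dp token lattice) to full-resolution per-class scores with
N+1 channels, channel 0 being background:

* **MF** (multi-level fusion): taps ``n_tap`` evenly spaced encoder layers
  (Ln/n_tap, 2Ln/n_tap, ..., Ln), runs each through its own
  conv-BN-ReLU x2 block followed by one trilinear x Hp upsampling,
  concatenates the branches on channels and applies a 1x1x1 head.
* **P3DA** (parallel 3D atrous): upsamples the final layer's features to
  full resolution and runs four parallel branches -- a 1x1x1 conv and
  3x3x3 convs at dilation 6, 12, 18 -- each with BN+ReLU; branch outputs
  are concatenated and reduced by two 1x1x1 convs.

Per-view predictions live in their view's frame; :func:`fuse_views`
realigns XZ/YZ back to the canonical grid (spatial axes only) and sums the
three score fields element-wise.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autodiff import Tensor, concat, relu, upsample3d
from .multiview import View, realign_spatial

__all__ = ["MFDecoder", "P3DADecoder", "fuse_views", "tokens_to_lattice"]


def tokens_to_lattice(tokens: Tensor, grid) -> Tensor:
    """(B, L, C) row-major token sequence -> (B, C, gh, gw, gd) feature grid."""
    b, l, c = tokens.data.shape
    gh, gw, gd = grid
    if gh * gw * gd != l:
        raise ValueError(f"grid {grid} incompatible with L={l}")
    return tokens.reshape(b, gh, gw, gd, c).transpose((0, 4, 1, 2, 3))


class _ConvBnRelu(nn.Module):
    def __init__(self, cin, cout, k, dilation, rng):
        super().__init__()
        self.conv = nn.Conv3d(cin, cout, k, dilation=dilation, rng=rng)
        self.norm = nn.BatchNorm3d(cout)

    def forward(self, x):
        return relu(self.norm(self.conv(x)))


class MFDecoder(nn.Module):
    """Multi-level fusion head.

    Each tapped layer runs through its own branch of two conv-BN-ReLU
    stages and one trilinear x patch_factor upsampling; ``upsample_at``
    places the upsampling layer within the branch ("pre" = before both
    convs, "mid" = between them, "post" = after both).  With "mid"/"pre"
    the 3x3x3 kernels operate at voxel resolution and can refine
    sub-patch boundaries instead of only blending lattice-level blocks.
    """

    def __init__(self, channels: int, n_classes: int, layers: int,
                 patch_factor: int = 4, n_tap: int = 4, upsample_at: str = "mid",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if layers % n_tap:
            raise ValueError(f"n_tap={n_tap} must divide the layer count {layers}")
        if upsample_at not in ("pre", "mid", "post"):
            raise ValueError(f"upsample_at must be pre|mid|post, got {upsample_at!r}")
        self.taps = tuple(layers // n_tap * (i + 1) - 1 for i in range(n_tap))
        # channel schedule: convs before the upsampling layer keep C, convs
        # at voxel resolution narrow to C/4 (decoder convention: trade
        # width for resolution)
        slim = max(channels // 4, n_classes + 1)
        if upsample_at == "post":
            widths_a, widths_b = (channels, channels), (channels, channels)
        else:  # narrow before upsampling so voxel-resolution convs stay cheap
            widths_a, widths_b = (channels, slim), (slim, slim)
        self.conv_a = [_ConvBnRelu(widths_a[0], widths_a[1], 3, 1, rng)
                       for _ in range(n_tap)]
        self.conv_b = [_ConvBnRelu(widths_b[0], widths_b[1], 3, 1, rng)
                       for _ in range(n_tap)]
        self.head = nn.Conv3d(n_tap * widths_b[1], n_classes + 1, 1, rng=rng)
        self.patch_factor = patch_factor
        self.n_tap = n_tap
        self.upsample_at = upsample_at

    def forward(self, layer_feats: list[Tensor], grid) -> Tensor:
        """Per-layer token features -> (B, N+1, H, W, D) logits."""
        outs = []
        for tap, conv_a, conv_b in zip(self.taps, self.conv_a, self.conv_b):
            x = tokens_to_lattice(layer_feats[tap], grid)
            if self.upsample_at == "pre":
                x = upsample3d(x, self.patch_factor)
            x = conv_a(x)
            if self.upsample_at == "mid":
                x = upsample3d(x, self.patch_factor)
            x = conv_b(x)
            if self.upsample_at == "post":
                x = upsample3d(x, self.patch_factor)
            outs.append(x)
        return self.head(concat(outs, axis=1))


class P3DADecoder(nn.Module):
    dilation_rates = (1, 6, 12, 18)

    def __init__(self, channels: int, n_classes: int, patch_factor: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        branches = []
        for rate in self.dilation_rates:
            if rate == 1:
                branches.append(_ConvBnRelu(channels, channels, 1, 1, rng))
            else:
                branches.append(_ConvBnRelu(channels, channels, 3, rate, rng))
        self.branches = branches
        self.fuse1 = nn.Conv3d(4 * channels, channels, 1, rng=rng)
        self.fuse2 = nn.Conv3d(channels, n_classes + 1, 1, rng=rng)
        self.patch_factor = patch_factor

    def forward(self, layer_feats: list[Tensor], grid) -> Tensor:
        x = tokens_to_lattice(layer_feats[-1], grid)
        x = upsample3d(x, self.patch_factor)  # back to the original resolution
        outs = [branch(x) for branch in self.branches]
        y = relu(self.fuse1(concat(outs, axis=1)))
        return self.fuse2(y)


def fuse_views(view_logits: dict) -> Tensor:
    """Element-wise sum of per-view logits after realignment to canonical.

    ``view_logits`` maps :class:`View` to (B, N+1, h, w, d) Tensors in each
    view's own frame; the class axis is untouched by realignment.
    """
    fused = None
    shape = None
    for view, logits in view_logits.items():
        perm = realign_spatial(View(view))
        aligned = logits.transpose((0, 1) + tuple(a + 2 for a in perm))
        if shape is None:
            shape = aligned.data.shape
        elif aligned.data.shape != shape:
            raise ValueError(
                f"view {view} logits realign to {aligned.data.shape}, expected {shape}"
            )
        fused = aligned if fused is None else fused + aligned
    if fused is None:
        raise ValueError("no views to fuse")
    return fused
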