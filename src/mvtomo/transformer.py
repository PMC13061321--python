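"""Graph-guided transformer encoder.

The encoder is a pre-norm ViT-style stack applied independently per view
(weights shared across views; only the position tables differ).  Its first
layer is *guided*: the K graph nodes from the context encoder act as the
attention queries against the layer-normalized tokens, producing K node
summaries.  Because a K-sequence cannot be added residually to L tokens,
the summaries are redistributed back onto tokens through the transpose of
the attention logits, renormalized over nodes (an L x K softmax), and the
redistributed update is added residually to the raw tokens.  The
redistribution step is isolated in :func:`redistribute` so alternative
readings can be swapped in.

Layers 2..Ln are standard pre-norm self-attention + MLP blocks (expansion
ratio 4, GELU).  All per-layer outputs are returned: the multi-level
fusion decoder taps intermediate layers, the atrous decoder uses the last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, gelu, softmax

__all__ = ["EncoderConfig", "Attention", "redistribute", "GuidedLayer",
           "StandardLayer", "ViewEncoder"]


@dataclass
class EncoderConfig:
    layers: int = 12       # Ln
    channels: int = 256    # hidden dimension C
    heads: int = 16
    mlp_ratio: int = 4

    def __post_init__(self):
        if self.channels % self.heads:
            raise ValueError(
                f"channels {self.channels} not divisible by heads {self.heads}"
            )


def _split_heads(x: Tensor, heads: int) -> Tensor:
    b, l, c = x.data.shape
    return x.reshape(b, l, heads, c // heads).transpose((0, 2, 1, 3))


def _merge_heads(x: Tensor) -> Tensor:
    b, h, l, d = x.data.shape
    return x.transpose((0, 2, 1, 3)).reshape(b, l, h * d)


class Attention(nn.Module):
    """Multi-head attention; queries may come from a different sequence."""

    def __init__(self, channels: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.wq = nn.Linear(channels, channels, rng=rng)
        self.wk = nn.Linear(channels, channels, rng=rng)
        self.wv = nn.Linear(channels, channels, rng=rng)
        self.proj = nn.Linear(channels, channels, rng=rng)
        self.heads = heads
        self.scale = float((channels // heads) ** -0.5)

    def scores(self, query: Tensor, keys: Tensor) -> Tensor:
        q = _split_heads(self.wq(query), self.heads)
        k = _split_heads(self.wk(keys), self.heads)
        return (q @ k.transpose((0, 1, 3, 2))) * self.scale  # (B, h, Lq, Lk)

    def forward(self, query: Tensor, keys: Tensor, values: Tensor) -> Tensor:
        s = self.scores(query, keys)
        v = _split_heads(self.wv(values), self.heads)
        out = softmax(s, axis=-1) @ v
        return self.proj(_merge_heads(out))


def redistribute(scores: Tensor, summaries: Tensor) -> Tensor:
    """Map K node summaries back onto L tokens.

    ``scores`` are the raw attention logits (B, h, K, L); the transpose is
    renormalized over the node axis (softmax over K) so each token receives
    a convex combination of the per-head node summaries (B, h, K, d)."""
    weights = softmax(scores, axis=-2)          # over the node axis K
    return weights.transpose((0, 1, 3, 2)) @ summaries  # (B, h, L, d)


class GuidedLayer(nn.Module):
    """First encoder layer: node-query cross-attention + redistribution."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        c = cfg.channels
        self.norm1 = nn.LayerNorm(c)
        self.attn = Attention(c, cfg.heads, rng)
        self.norm2 = nn.LayerNorm(c)
        self.fc1 = nn.Linear(c, cfg.mlp_ratio * c, rng=rng)
        self.fc2 = nn.Linear(cfg.mlp_ratio * c, c, rng=rng)
        self.heads = cfg.heads

    def forward(self, tokens: Tensor, nodes: Tensor) -> Tensor:
        if nodes.data.shape[-1] != tokens.data.shape[-1]:
            raise ValueError(
                f"node channels {nodes.data.shape[-1]} != token channels "
                f"{tokens.data.shape[-1]}"
            )
        normed = self.norm1(tokens)
        s = self.attn.scores(nodes, normed)               # (B, h, K, L)
        v = _split_heads(self.attn.wv(normed), self.heads)
        z = softmax(s, axis=-1) @ v                       # node summaries (B, h, K, d)
        update = self.attn.proj(_merge_heads(redistribute(s, z)))
        x = update + tokens                               # residual on raw tokens
        return self.fc2(gelu(self.fc1(self.norm2(x)))) + x


class StandardLayer(nn.Module):
    """Pre-norm self-attention block with residuals (layers n >= 2)."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        c = cfg.channels
        self.norm1 = nn.LayerNorm(c)
        self.attn = Attention(c, cfg.heads, rng)
        self.norm2 = nn.LayerNorm(c)
        self.fc1 = nn.Linear(c, cfg.mlp_ratio * c, rng=rng)
        self.fc2 = nn.Linear(cfg.mlp_ratio * c, c, rng=rng)

    def forward(self, tokens: Tensor) -> Tensor:
        n = self.norm1(tokens)
        x = self.attn(n, n, n) + tokens
        return self.fc2(gelu(self.fc1(self.norm2(x)))) + x


class ViewEncoder(nn.Module):
    """Ln-layer encoder returning every layer's token sequence.

    With ``use_graph=False`` the first layer degrades to a standard
    self-attention layer (the graph-guidance ablation switch)."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator,
                 use_graph: bool = True):
        super().__init__()
        self.cfg = cfg
        self.use_graph = use_graph
        if use_graph:
            self.first = GuidedLayer(cfg, rng)
        else:
            self.first = StandardLayer(cfg, rng)
        self.rest = [StandardLayer(cfg, rng) for _ in range(cfg.layers - 1)]

    def forward(self, tokens: Tensor, nodes: Tensor | None = None) -> list[Tensor]:
        if self.use_graph:
            if nodes is None:
                raise ValueError("graph-guided encoder requires node queries")
            x = self.first(tokens, nodes)
        else:
            x = self.first(tokens)
        feats = [x]
        for layer in self.rest:
            x = layer(x)
            feats.append(x)
        return feats
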