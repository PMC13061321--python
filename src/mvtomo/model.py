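"""The assembled multi-view graph-guided segmentation model.

Forward pass for a batch of cubic patch volumes:

1. the context encoder produces a C-channel feature grid from the
   canonical frame; k-means over the flattened grid yields K graph nodes
   (per sample, assignments detached, means differentiable);
2. each selected view reorders the volume into its frame, patchifies it
   (4^3 by default), projects patches through the *shared* linear layer
   and adds that view's *own* position table;
3. the shared Ln-layer transformer encodes each view, the first layer
   guided by the graph nodes;
4. the configured decoder head maps token features to per-class logits in
   each view's frame, and the three fields are realigned and summed into
   the fused canonical prediction.

A separate reconstruction pass re-embeds the views with one view masked
and runs the lightweight reconstruction decoder (see :mod:`mvtomo.vsl`).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor
from .context_graph import ContextEncoder, graph_nodes_batch
from .decoders import MFDecoder, P3DADecoder, fuse_views
from .multiview import View, patchify, to_view
from .transformer import EncoderConfig, ViewEncoder
from .vsl import MaskPlan, ReconDecoder, apply_mask, plan_mask, recon_loss

__all__ = ["ModelConfig", "MultiViewSegmenter", "ALL_VIEWS"]

ALL_VIEWS = (View.XY, View.XZ, View.YZ)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the full-scale configuration (Ln=12, C=256, 16 heads,
    K=16 clusters, 4^3 patches on 32^3 inputs, mask rate 0.5);
    :meth:`toy` is the desk-scale profile used by the scaled-down
    experiments.
    """

    input_size: int = 32          # cubic patch edge length
    patch_size: int = 4           # Hp = Wp = Dp
    n_classes: int = 1            # foreground classes (background is extra)
    channels: int = 256           # C
    layers: int = 12              # Ln
    heads: int = 16
    k_clusters: int = 16          # K
    n_tap: int = 4                # MF decoder taps
    decoder: str = "mf"           # "mf" | "p3da"
    views: tuple = ("XY", "XZ", "YZ")
    use_graph: bool = True
    use_vsl: bool = True
    mask_rate: float = 0.5        # eta
    vsl_depth: int = 2
    init_seed: int = 0

    def __post_init__(self):
        if self.input_size % self.patch_size:
            raise ValueError(
                f"input size {self.input_size} not divisible by patch {self.patch_size}"
            )
        if self.decoder not in ("mf", "p3da"):
            raise ValueError(f"decoder must be 'mf' or 'p3da', got {self.decoder!r}")
        self.views = tuple(View(v) for v in self.views)
        if not self.views:
            raise ValueError("at least one view is required")

    @property
    def seq_length(self) -> int:
        return (self.input_size // self.patch_size) ** 3

    @property
    def grid(self) -> tuple[int, int, int]:
        g = self.input_size // self.patch_size
        return (g, g, g)

    @classmethod
    def toy(cls, **overrides) -> "ModelConfig":
        base = dict(input_size=16, patch_size=4, n_classes=1, channels=32,
                    layers=2, heads=4, k_clusters=4, n_tap=2, decoder="mf")
        base.update(overrides)
        return cls(**base)

    def to_json(self) -> str:
        d = asdict(self)
        d["views"] = [v.value for v in self.views]
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


@dataclass
class SegmentationOutput:
    view_logits: dict            # View -> (B, N+1, h, w, d) Tensor, view frame
    fused: Tensor                # (B, N+1, H, W, D) canonical frame
    layer_feats: dict            # View -> list of per-layer (B, L, C) Tensors
    nodes: Tensor | None = None  # (B, K, C)
    graph_info: list = field(default_factory=list)


class MultiViewSegmenter(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.init_seed)
        p3 = cfg.patch_size**3
        self.patch_embed = nn.Linear(p3, cfg.channels, rng=rng)  # shared across views
        for view in ALL_VIEWS:
            table = nn.Parameter(rng.normal(0.0, 0.02, size=(cfg.seq_length, cfg.channels)))
            setattr(self, f"pos_{view.value}", table)
        self.context = ContextEncoder(cfg.channels, rng=rng)
        enc_cfg = EncoderConfig(cfg.layers, cfg.channels, cfg.heads)
        self.encoder = ViewEncoder(enc_cfg, rng, use_graph=cfg.use_graph)
        if cfg.decoder == "mf":
            self.decoder = MFDecoder(cfg.channels, cfg.n_classes, cfg.layers,
                                     patch_factor=cfg.patch_size, n_tap=cfg.n_tap, rng=rng)
        else:
            self.decoder = P3DADecoder(cfg.channels, cfg.n_classes,
                                       patch_factor=cfg.patch_size, rng=rng)
        self.recon = ReconDecoder(cfg.channels, cfg.heads, p3,
                                  depth=cfg.vsl_depth, rng=rng)

    # -- helpers -----------------------------------------------------------
    def pos_table(self, view) -> Tensor:
        return getattr(self, f"pos_{View(view).value}")

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        s = self.cfg.input_size
        if x.shape[1:] != (s, s, s):
            raise ValueError(f"expected (B, {s}, {s}, {s}) input, got {x.shape}")
        return x

    def raw_patches(self, x: np.ndarray, view) -> np.ndarray:
        """(B, L, p^3) flattened patch contents of a batch in a view frame."""
        p = self.cfg.patch_size
        return np.stack([patchify(to_view(v, view), p) for v in x])

    def embed_view(self, x: np.ndarray, view) -> Tensor:
        raw = self.raw_patches(x, view)
        return self.patch_embed(Tensor(raw)) + self.pos_table(view)

    def compute_nodes(self, x: np.ndarray, seed: int = 0):
        feats = self.context(Tensor(x[:, None]))
        return graph_nodes_batch(feats, self.cfg.k_clusters, seed=seed)

    # -- main passes --------------------------------------------------------
    def segment(self, x: np.ndarray, kmeans_seed: int = 0) -> SegmentationOutput:
        x = self._check_input(x)
        nodes, info = (None, [])
        if self.cfg.use_graph:
            nodes, info = self.compute_nodes(x, seed=kmeans_seed)
        layer_feats = {}
        view_logits = {}
        grid = self.cfg.grid
        for view in self.cfg.views:
            tokens = self.embed_view(x, view)
            feats = self.encoder(tokens, nodes)
            layer_feats[view] = feats
            view_logits[view] = self.decoder(feats, grid)
        fused = fuse_views(view_logits)
        return SegmentationOutput(view_logits, fused, layer_feats, nodes, info)

    def reconstruct(self, x: np.ndarray, seed: int, kmeans_seed: int = 0,
                    reuse_feats: dict | None = None,
                    nodes: Tensor | None = None) -> tuple[Tensor, Tensor, MaskPlan]:
        """Masked-view reconstruction pass.

        Returns ``(loss, reconstructed, plan)``; the masked view is drawn
        uniformly among the three views.  ``reuse_feats`` may supply final
        encoder features of *unmasked* views from a segmentation pass on
        the same batch (their tokens enter the reconstruction decoder
        unmodified either way, so this only saves recomputation).
        """
        x = self._check_input(x)
        plan = plan_mask(self.cfg.seq_length, self.cfg.mask_rate, seed, views=ALL_VIEWS)
        reuse = reuse_feats or {}
        if nodes is None and self.cfg.use_graph:
            nodes, _ = self.compute_nodes(x, seed=kmeans_seed)
        final_feats = {}
        target_raw = self.raw_patches(x, plan.masked_view)
        for view in ALL_VIEWS:
            if view != plan.masked_view and view in reuse:
                final_feats[view] = reuse[view]
                continue
            raw = target_raw if view == plan.masked_view else self.raw_patches(x, view)
            tokens = self.patch_embed(Tensor(raw)) + self.pos_table(view)
            if view == plan.masked_view:
                tokens = apply_mask(tokens, plan, self.recon.mask_token,
                                    self.pos_table(view))
            final_feats[view] = self.encoder(tokens, nodes)[-1]
        rec = self.recon(final_feats, plan, ALL_VIEWS)
        loss = recon_loss(rec, target_raw, plan)
        return loss, rec, plan
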