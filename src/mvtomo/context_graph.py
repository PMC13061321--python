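"""Context encoder and k-means visual-graph construction.

A lightweight convolutional stream runs in parallel with the transformer:
three conv(3x3x3) -> batch-norm -> ReLU blocks, each with stride 2, map a
single-channel patch volume to a C-channel feature grid (a 32^3 patch
yields a 4^3 lattice of N = 64 feature vectors).  The flattened features
are clustered by Lloyd's k-means into K graph nodes -- cluster means of the
assigned features -- which the first transformer layer uses as attention
queries.

Clustering details (all deterministic given the seed):

* init: first center drawn uniformly from the points, the rest by
  farthest-point selection (max-min distance, first index on ties);
* assignment: nearest center by squared Euclidean distance, ties broken
  toward the smallest cluster index;
* empty clusters are re-seeded from the point farthest from its own
  center, then assignments are recomputed;
* the within-cluster objective is non-increasing across iterations and the
  run stops when its relative improvement falls below ``tol``.

The assignment matrix is treated as non-differentiable; gradients reach
the context encoder through the cluster-mean computation with assignments
detached (straight-through on the means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor, relu

__all__ = ["ContextEncoder", "GraphNodes", "kmeans_nodes", "graph_nodes_batch"]


class ContextEncoder(nn.Module):
    """Three stride-2 conv/BN/ReLU blocks: (B, 1, H, W, D) -> (B, C, H/8, W/8, D/8)."""

    n_blocks = 3

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        widths = [max(channels // 4, 1), max(channels // 2, 1), channels]
        convs, norms = [], []
        cin = 1
        for w in widths:
            convs.append(nn.Conv3d(cin, w, 3, stride=2, rng=rng))
            norms.append(nn.BatchNorm3d(w))
            cin = w
        self.convs = convs
        self.norms = norms
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        if min(x.data.shape[2:]) < 2**self.n_blocks:
            raise ValueError(
                f"input spatial extents {x.data.shape[2:]} smaller than the total "
                f"downsampling factor {2 ** self.n_blocks}"
            )
        for conv, norm in zip(self.convs, self.norms):
            x = relu(norm(conv(x)))
        return x


@dataclass
class GraphNodes:
    """K cluster-mean feature vectors with their binary assignment matrix."""

    nodes: np.ndarray            # (K, C) cluster means
    centers: np.ndarray          # (K, C) final Lloyd centers (== nodes)
    assignments: np.ndarray      # (N,) cluster index per feature
    R: np.ndarray                # (N, K) one-hot assignment, rows sum to 1
    objective_history: list = field(default_factory=list)


def _objective(features: np.ndarray, centers: np.ndarray, assign: np.ndarray) -> float:
    return float(((features - centers[assign]) ** 2).sum())


def _assign(features: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # squared distances; argmin returns the smallest index on ties
    d2 = ((features[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _farthest_point_init(features: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = features.shape[0]
    centers = [features[int(rng.integers(n))]]
    d2 = ((features - centers[0]) ** 2).sum(axis=1)
    for _ in range(1, k):
        idx = int(d2.argmax())  # first index on ties
        centers.append(features[idx])
        d2 = np.minimum(d2, ((features - centers[-1]) ** 2).sum(axis=1))
    return np.stack(centers)


def kmeans_nodes(features: np.ndarray, k: int, seed: int = 0,
                 max_iter: int = 20, tol: float = 1e-4) -> GraphNodes:
    """Cluster N feature vectors (N, C) into K graph nodes by Lloyd's method."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2:
        raise ValueError(f"features must be (N, C), got {features.shape}")
    if not np.all(np.isfinite(features)):
        raise ValueError("non-finite features")
    n = features.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= K <= N, got K={k}, N={n}")
    rng = np.random.default_rng(seed)
    centers = _farthest_point_init(features, k, rng)
    assign = _assign(features, centers)
    history = [_objective(features, centers, assign)]
    for _ in range(max_iter):
        # update step: means of assigned features; re-seed empty clusters
        for kk in range(k):
            mask = assign == kk
            if mask.any():
                centers[kk] = features[mask].mean(axis=0)
            else:
                far = int(((features - centers[assign]) ** 2).sum(axis=1).argmax())
                centers[kk] = features[far]
        assign = _assign(features, centers)
        obj = _objective(features, centers, assign)
        history.append(obj)
        prev = history[-2]
        if prev - obj <= tol * max(prev, 1e-12):
            break
    # final means so that g_k is exactly the mean of its assigned features
    for kk in range(k):
        mask = assign == kk
        if mask.any():
            centers[kk] = features[mask].mean(axis=0)
    assign = _assign(features, centers)
    # guarantee no empty cluster even for degenerate (duplicate-point)
    # inputs: give each empty cluster its own farthest point, never taking
    # the last member of a donor cluster
    for kk in range(k):
        if (assign == kk).any():
            continue
        counts = np.bincount(assign, minlength=k)
        eligible = np.where(counts[assign] >= 2)[0]
        d2 = ((features[eligible] - centers[assign[eligible]]) ** 2).sum(axis=1)
        steal = int(eligible[int(d2.argmax())])
        assign[steal] = kk
    for kk in range(k):
        centers[kk] = features[assign == kk].mean(axis=0)
    r = np.zeros((n, k), dtype=np.float32)
    r[np.arange(n), assign] = 1.0
    nodes = centers.astype(np.float32)
    return GraphNodes(nodes, nodes.copy(), assign, r, history)


def graph_nodes_batch(features: Tensor, k: int, seed: int = 0,
                      max_iter: int = 20, tol: float = 1e-4):
    """Cluster a batched feature grid (B, C, h, w, d) into node tensors.

    Returns ``(nodes, infos)`` where ``nodes`` is a (B, K, C) Tensor that is
    differentiable through the features (assignments detached) and
    ``infos`` the per-sample :class:`GraphNodes`.
    """
    b, c = features.data.shape[:2]
    n = int(np.prod(features.data.shape[2:]))
    flat = features.reshape(b, c, n).transpose((0, 2, 1))  # (B, N, C)
    infos = []
    rnorm = np.zeros((b, k, n), dtype=np.float32)
    for i in range(b):
        info = kmeans_nodes(flat.data[i], k, seed=seed + i, max_iter=max_iter, tol=tol)
        infos.append(info)
        counts = info.R.sum(axis=0)  # no empty clusters by construction
        rnorm[i] = (info.R / counts[None, :]).T
    nodes = Tensor(rnorm) @ flat  # (B, K, N) @ (B, N, C) -> (B, K, C)
    return nodes, infos
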