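"""Observation views, patchification and token embedding.

A volume on the canonical (H, W, D) grid can be observed along three
orthogonal perspectives.  XY is the canonical frame; the YZ view reorders
axes to (H, D, W) and the XZ view to (D, W, H).  Both reorderings are pure
axis permutations (and involutions), so the voxel multiset is preserved and
``from_view(to_view(x, v), v) == x`` bitwise.

In each view frame the volume is split into cubic patches of shape
(Hp, Wp, Dp), giving L = H/Hp * W/Wp * D/Dp tokens in row-major lattice
order.  Tokens are the linear projection of the flattened patch plus that
view's learnable position vector; the projection is shared across views
while each view keeps its own position table, so view identity is carried
entirely by the position embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "View",
    "VIEW_AXES",
    "to_view",
    "from_view",
    "realign_spatial",
    "patchify",
    "unpatchify",
    "token_grid",
    "TokenBatch",
    "embed",
]


class View(str, Enum):
    XY = "XY"
    XZ = "XZ"
    YZ = "YZ"


# axis order of each view frame, expressed as a permutation of (H, W, D)
VIEW_AXES: dict[View, tuple[int, int, int]] = {
    View.XY: (0, 1, 2),  # canonical
    View.YZ: (0, 2, 1),  # (H, D, W)
    View.XZ: (2, 1, 0),  # (D, W, H)
}


def _axes(view) -> tuple[int, int, int]:
    try:
        return VIEW_AXES[View(view)]
    except (KeyError, ValueError):
        raise ValueError(f"unknown view {view!r}; expected one of XY, XZ, YZ") from None


def to_view(data: np.ndarray, view) -> np.ndarray:
    """Reorder a canonical-frame array into the given view frame."""
    return np.transpose(data, _axes(view))


def from_view(data: np.ndarray, view) -> np.ndarray:
    """Exact inverse of :func:`to_view`."""
    return np.transpose(data, np.argsort(_axes(view)))


def realign_spatial(view) -> tuple[int, int, int]:
    """Permutation carrying the view frame's spatial axes back to canonical.

    Intended for score fields with extra leading/trailing axes: apply it to
    the three spatial axes only, leaving the class axis untouched.
    """
    return tuple(int(a) for a in np.argsort(_axes(view)))


def token_grid(shape, patch) -> tuple[int, int, int]:
    patch = tuple(int(p) for p in (patch if np.ndim(patch) else (patch,) * 3))
    if any(s % p for s, p in zip(shape, patch)):
        raise ValueError(f"shape {tuple(shape)} not divisible by patch {patch}")
    return tuple(s // p for s, p in zip(shape, patch))


def patchify(data: np.ndarray, patch) -> np.ndarray:
    """Split a 3D array into L flattened cubic patches.

    Returns an (L, Hp*Wp*Dp) array in row-major lattice order; lossless
    (:func:`unpatchify` inverts it).
    """
    patch = tuple(int(p) for p in (patch if np.ndim(patch) else (patch,) * 3))
    gh, gw, gd = token_grid(data.shape, patch)
    ph, pw, pd = patch
    x = data.reshape(gh, ph, gw, pw, gd, pd)
    x = x.transpose(0, 2, 4, 1, 3, 5)  # (gh, gw, gd, ph, pw, pd)
    return np.ascontiguousarray(x.reshape(gh * gw * gd, ph * pw * pd))


def unpatchify(tokens: np.ndarray, grid, patch) -> np.ndarray:
    """Inverse of :func:`patchify`."""
    patch = tuple(int(p) for p in (patch if np.ndim(patch) else (patch,) * 3))
    gh, gw, gd = grid
    ph, pw, pd = patch
    x = tokens.reshape(gh, gw, gd, ph, pw, pd)
    x = x.transpose(0, 3, 1, 4, 2, 5)
    return np.ascontiguousarray(x.reshape(gh * ph, gw * pw, gd * pd))


@dataclass
class TokenBatch:
    """Embedded token sequence for one view: ``tokens`` is (B, L, C)."""

    view: View
    tokens: object  # autodiff.Tensor
    grid: tuple[int, int, int]
    patch: tuple[int, int, int]

    @property
    def length(self) -> int:
        g = self.grid
        return g[0] * g[1] * g[2]


def embed(raw_patches: np.ndarray, view, projection, table, grid=None, patch=None) -> TokenBatch:
    """Project raw flattened patches to C channels and add the view's
    position table.

    ``raw_patches`` is (B, L, Hp*Wp*Dp) (or (L, p3) for a single volume),
    ``projection`` a :class:`mvtomo.nn.Linear` shared across views and
    ``table`` the (L, C) position parameter of this view.  ``grid`` and
    ``patch`` record the token-lattice geometry when known.
    """
    from .autodiff import Tensor

    view = View(view)
    raw = np.asarray(raw_patches, dtype=np.float32)
    if raw.ndim == 2:
        raw = raw[None]
    L = raw.shape[1]
    if table.data.shape[0] != L:
        raise ValueError(
            f"position table has {table.data.shape[0]} entries but sequence length is {L}"
        )
    tokens = projection(Tensor(raw)) + table
    grid = tuple(grid) if grid is not None else (L, 1, 1)
    patch = tuple(patch) if patch is not None else (1, 1, 1)
    return TokenBatch(view, tokens, grid, patch)
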