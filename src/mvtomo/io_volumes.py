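"""Volumes, label volumes, overlap tiling and smooth-window tile fusion.

A :class:`Volume` is a 3D grayscale scalar field on the canonical
``(H, W, D)`` voxel grid; a :class:`LabelVolume` is a co-registered integer
class field with 0 reserved for background.  Large volumes are processed by
cutting them into cubic patches (non-overlapping for training, 50 %
overlap for inference) and reassembling per-class score blocks with a
raised-cosine weight window so that overlapping predictions blend into a
partition of unity.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .mrc import MrcFormatError, read_mrc, write_mrc

__all__ = [
    "Volume",
    "LabelVolume",
    "PatchGrid",
    "WeightWindow",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "tile",
    "make_window",
    "fuse_tiles",
    "read_particles",
    "write_particles",
]


@dataclass
class Volume:
    """3D scalar field with optional physical voxel spacing (Angstrom/voxel)."""

    data: np.ndarray
    voxel_size: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with positive extents, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass
class LabelVolume:
    """Integer class field, values in {0..n_classes} with 0 = background."""

    labels: np.ndarray
    n_classes: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        if self.labels.min() < 0 or self.labels.max() > self.n_classes:
            raise ValueError(
                f"labels must lie in 0..{self.n_classes}, got range "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)


@dataclass
class PatchGrid:
    """Ordered tiling of a parent volume into equally-sized patches."""

    patches: list  # list of (origin (3-tuple), np.ndarray of patch shape)
    stride: tuple[int, int, int]
    parent_shape: tuple[int, int, int]
    padded_shape: tuple[int, int, int]
    pad: tuple[int, int, int] = (0, 0, 0)


@dataclass
class WeightWindow:
    """Separable raised-cosine blending window, 1 at the center, >0 everywhere."""

    weights: np.ndarray = field(repr=False)


def read_volume(path) -> Volume:
    """Read an MRC volume (modes 0/1/2/6), converting data to float32."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    data, voxel_size = read_mrc(path)
    data = np.asarray(data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise MrcFormatError(f"{path}: data block contains NaN/Inf voxels")
    return Volume(data, voxel_size)


def write_volume(path, volume: Volume, mode: int = 2) -> None:
    write_mrc(path, volume.data, volume.voxel_size, mode=mode)


def read_labels(path, n_classes: int) -> LabelVolume:
    """Read an integer-mode MRC file as a label volume."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    data, _ = read_mrc(path)
    if not np.issubdtype(data.dtype, np.integer):
        data = np.asarray(data)
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise MrcFormatError(f"{path}: non-integer values in a label volume")
        data = rounded.astype(np.int64)
    return LabelVolume(data.astype(np.int64), n_classes)


def write_labels(path, labels: LabelVolume, voxel_size: float | None = None) -> None:
    lab = labels.labels
    mode = 0 if lab.max(initial=0) < 128 and lab.min(initial=0) >= -128 else 1
    write_mrc(path, lab, voxel_size, mode=mode)


def _axis_starts(extent: int, patch: int, stride: int) -> list[int]:
    starts = list(range(0, extent - patch + 1, stride))
    if starts[-1] != extent - patch:
        starts.append(extent - patch)  # shift final patch inward to stay in bounds
    return starts


def tile(volume: Volume, patch, overlap_fraction: float = 0.0) -> PatchGrid:
    """Cut a volume into patches on a stride lattice.

    ``overlap_fraction=0`` gives a disjoint cover (the volume is zero-padded
    up to the next patch multiple when extents do not divide);
    ``overlap_fraction=0.5`` gives stride ``patch/2`` with the final patch
    per axis shifted inward so no patch exceeds the volume.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    patch = tuple(int(p) for p in (patch if np.ndim(patch) else (patch,) * 3))
    data = volume.data
    shape = data.shape
    if any(p > s for p, s in zip(patch, shape)):
        raise ValueError(f"patch {patch} larger than volume {shape}")
    pad = (0, 0, 0)
    if overlap_fraction == 0:
        pad = tuple((-s) % p for s, p in zip(shape, patch))
        if any(pad):
            data = np.pad(data, [(0, q) for q in pad])
        stride = patch
    else:
        stride = tuple(max(1, int(round(p * (1 - overlap_fraction)))) for p in patch)
    padded_shape = data.shape
    patches = []
    for i in _axis_starts(padded_shape[0], patch[0], stride[0]):
        for j in _axis_starts(padded_shape[1], patch[1], stride[1]):
            for k in _axis_starts(padded_shape[2], patch[2], stride[2]):
                block = data[i : i + patch[0], j : j + patch[1], k : k + patch[2]]
                patches.append(((i, j, k), block))
    return PatchGrid(patches, stride, tuple(shape), tuple(padded_shape), pad)


def make_window(patch, eps: float = 1e-3) -> WeightWindow:
    """Separable raised-cosine window, normalized to 1 at the center and
    floored at ``eps`` so border voxels keep nonzero blending weight."""
    patch = tuple(int(p) for p in (patch if np.ndim(patch) else (patch,) * 3))
    if any(p < 2 for p in patch):
        raise ValueError(f"window sizes must be >= 2, got {patch}")
    axes = []
    for n in patch:
        i = np.arange(n, dtype=np.float64)
        w = 0.5 - 0.5 * np.cos(2.0 * np.pi * (i + 0.5) / n)
        w /= w.max()
        axes.append(np.maximum(w, eps))
    weights = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return WeightWindow(weights.astype(np.float32))


def fuse_tiles(patch_scores, window: WeightWindow, parent_shape) -> np.ndarray:
    """Blend per-patch score blocks into a parent-shaped field.

    Each element of ``patch_scores`` is ``(origin, block)`` where ``block``
    has the window's spatial shape plus an optional trailing class axis.
    Output voxel value is sum(window * score) / sum(window) over covering
    patches; a voxel covered by exactly one patch reproduces that patch's
    scores exactly.
    """
    parent_shape = tuple(int(s) for s in parent_shape)
    w = window.weights
    wshape = w.shape
    trailing: tuple[int, ...] | None = None
    for origin, block in patch_scores:
        block = np.asarray(block)
        if block.shape[:3] != wshape:
            raise ValueError(f"block shape {block.shape} does not match window {wshape}")
        tr = block.shape[3:]
        if trailing is None:
            trailing = tr
        elif tr != trailing:
            raise ValueError("inconsistent trailing class axes across blocks")
        if any(o < 0 or o + p > s for o, p, s in zip(origin, wshape, parent_shape)):
            raise ValueError(f"block at {origin} exceeds parent shape {parent_shape}")
    if trailing is None:
        raise ValueError("no patches to fuse")
    num = np.zeros(parent_shape + trailing, dtype=np.float64)
    den = np.zeros(parent_shape, dtype=np.float64)
    wexp = w.astype(np.float64).reshape(wshape + (1,) * len(trailing))
    for origin, block in patch_scores:
        i, j, k = origin
        sl = (slice(i, i + wshape[0]), slice(j, j + wshape[1]), slice(k, k + wshape[2]))
        num[sl] += wexp * np.asarray(block, dtype=np.float64)
        den[sl] += w
    if np.any(den == 0):
        raise ValueError("some voxels are covered by zero patches")
    fused = num / den.reshape(parent_shape + (1,) * len(trailing))
    return fused.astype(np.float32)


def write_particles(path, records) -> None:
    """Write particle records as TSV: class_id, x, y, z, radius (0-based voxels)."""
    with open(path, "w") as fh:
        fh.write("class_id\tx\ty\tz\tradius\n")
        for rec in records:
            cid, (x, y, z), r = rec.class_id, rec.center, rec.radius
            fh.write(f"{cid}\t{x}\t{y}\t{z}\t{r}\n")


def read_particles(path):
    """Read a particle TSV written by :func:`write_particles`."""
    from .synthetic import Particle

    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("class_id"):
            raise ValueError(f"{path}: missing particle TSV header")
        for line in fh:
            if not line.strip():
                continue
            cid, x, y, z, r = line.split("\t")
            out.append(
                Particle(int(cid), (float(x), float(y), float(z)), float(r))
            )
    return out
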