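"""Evaluation metrics: overlap scores, particle picking, feature diversity.

mIoU and Dice average per-class scores over the classes present in either
volume (classes absent from both are skipped to avoid undefined 0/0
terms).  Particle picking follows the center-distance criterion: a
prediction is a true positive when its Euclidean distance to an unmatched
ground-truth center of the same class is strictly less than that
particle's radius; matching is greedy in increasing distance order with a
one-to-one constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_volumes import LabelVolume
from .synthetic import Particle

__all__ = ["ConfusionCounts", "confusion", "miou", "dice", "extract_centers",
           "PickingResult", "match_particles", "cos_sim", "fds"]


@dataclass
class ConfusionCounts:
    """Per-class overlap tallies between a predicted and a reference labeling."""

    classes: np.ndarray       # class ids present in pred or gt
    intersection: np.ndarray
    union: np.ndarray
    pred_size: np.ndarray
    gt_size: np.ndarray


def _as_labels(x) -> np.ndarray:
    return x.labels if isinstance(x, LabelVolume) else np.asarray(x)


def confusion(pred, gt) -> ConfusionCounts:
    p, g = _as_labels(pred), _as_labels(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    classes = np.union1d(np.unique(p), np.unique(g))
    inter, union, psz, gsz = [], [], [], []
    for c in classes:
        pm, gm = p == c, g == c
        i = int(np.logical_and(pm, gm).sum())
        inter.append(i)
        psz.append(int(pm.sum()))
        gsz.append(int(gm.sum()))
        union.append(psz[-1] + gsz[-1] - i)
    return ConfusionCounts(classes, np.array(inter), np.array(union),
                           np.array(psz), np.array(gsz))


def miou(pred, gt) -> float:
    """Mean per-class intersection-over-union."""
    c = confusion(pred, gt)
    return float(np.mean(c.intersection / c.union))


def dice(pred, gt) -> float:
    """Mean per-class Dice similarity 2|A∩B| / (|A| + |B|)."""
    c = confusion(pred, gt)
    return float(np.mean(2.0 * c.intersection / (c.pred_size + c.gt_size)))


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def extract_centers(pred, min_size: int = 1, radius: float = 0.0) -> list[Particle]:
    """Particle records from a labeled prediction.

    26-connected components per class; the center is the component centroid
    rounded to the nearest voxel; components below ``min_size`` voxels are
    dropped.  ``radius`` is attached to every record (predictions carry no
    intrinsic size; matching uses the ground-truth radius anyway).
    """
    lab = _as_labels(pred)
    out: list[Particle] = []
    for c in np.unique(lab):
        if c == 0:
            continue
        comp, n = ndimage.label(lab == c, structure=_STRUCT26)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=range(1, n + 1))
        centroids = ndimage.center_of_mass(lab == c, comp, index=range(1, n + 1))
        for size, cen in zip(sizes, centroids):
            if size < min_size:
                continue
            center = tuple(float(np.rint(v)) for v in cen)
            out.append(Particle(int(c), center, radius))
    return out


@dataclass
class PickingResult:
    tp: int
    fp: int
    fn: int
    matches: list  # (pred index, gt index, distance)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def match_particles(pred: list[Particle], gt: list[Particle]) -> PickingResult:
    """Greedy one-to-one matching of predictions to ground-truth centers.

    Candidate pairs share a class and have center distance strictly below
    the ground-truth radius; pairs are accepted in increasing distance
    order.  Unmatched predictions are false positives; unmatched ground
    truth are false negatives.
    """
    for g in gt:
        if g.radius < 0:
            raise ValueError(f"negative ground-truth radius {g.radius}")
    candidates = []
    for i, p in enumerate(pred):
        for j, g in enumerate(gt):
            if p.class_id != g.class_id:
                continue
            d = float(np.linalg.norm(np.subtract(p.center, g.center)))
            if d < g.radius:  # strict: distance == radius is not a match
                candidates.append((d, i, j))
    candidates.sort()
    used_p: set[int] = set()
    used_g: set[int] = set()
    matches = []
    for d, i, j in candidates:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        matches.append((i, j, d))
    tp = len(matches)
    return PickingResult(tp, len(pred) - tp, len(gt) - tp, matches)


def cos_sim(f1, f2) -> float:
    """Cosine similarity of two feature vectors."""
    a = np.asarray(f1, dtype=np.float64).ravel()
    b = np.asarray(f2, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm feature vector")
    return float(a @ b / (na * nb))


def fds(f1, f2) -> float:
    """Feature diversity score: mean squared Euclidean distance over
    paired feature vectors (N, C)."""
    a = np.asarray(f1, dtype=np.float64)
    b = np.asarray(f2, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    a = a.reshape(a.shape[0], -1)
    b = b.reshape(b.shape[0], -1)
    return float(np.mean(((a - b) ** 2).sum(axis=1)))
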