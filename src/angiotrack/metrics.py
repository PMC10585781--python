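"""Segmentation and detection evaluation utilities.

Dice overlap and average symmetric surface distance (ASD) compare a
candidate mask against a reference; accuracy and recall summarize
confusion counts from grading or bridge calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def dice(ref: np.ndarray, seg: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|), in [0, 1].

    Two empty masks are defined to agree perfectly (1.0).
    """
    a = np.asarray(ref) > 0
    b = np.asarray(seg) > 0
    if a.shape != b.shape:
        raise ValueError("dice: mask shapes differ")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbor
    (image-border foreground pixels count as boundary)."""
    m = np.asarray(mask) > 0
    eroded = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    ys, xs = np.nonzero(m & ~eroded)
    return np.stack([ys, xs], axis=1).astype(float)


def asd(ref: np.ndarray, seg: np.ndarray) -> float:
    """Average symmetric surface distance between two mask boundaries:

        ( Σ_a min_b ||a-b|| + Σ_b min_a ||b-a|| ) / (|S(A)| + |S(B)|)

    in pixels.  Both masks must be nonempty.
    """
    a = np.asarray(ref) > 0
    b = np.asarray(seg) > 0
    if a.shape != b.shape:
        raise ValueError("asd: mask shapes differ")
    if not a.any() or not b.any():
        raise ValueError("asd: masks must be nonempty")
    sa, sb = _boundary(a), _boundary(b)
    d_ab = cKDTree(sb).query(sa)[0]
    d_ba = cKDTree(sa).query(sb)[0]
    return float((d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb)))


def accuracy_recall(c: ConfusionCounts) -> tuple[float, float]:
    """(accuracy, recall) from confusion counts; an undefined rate
    (zero denominator) is returned as NaN."""
    total = c.tp + c.tn + c.fp + c.fn
    acc = (c.tp + c.tn) / total if total > 0 else math.nan
    rec = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    return acc, rec
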