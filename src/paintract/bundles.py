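"""Streamline containers and exhaustive ROI-combination bundle selection.

A streamline connects a combination of ROIs iff, for every ROI in the
combination, at least one of its supporting points lies inside that ROI.
Membership is point-wise: a segment that crosses an ROI between two outside
points does not count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .phantom import RoiSpec


@dataclass
class Tractogram:
    """Ordered polylines in world mm."""

    streamlines: list  # list of (n_i, 3) float arrays, n_i >= 2
    space: str = "world-mm"
    affine: np.ndarray | None = None  # reference grid, for TRK headers

    def __post_init__(self):
        cleaned = []
        for s in self.streamlines:
            a = np.asarray(s, dtype=float)
            if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 2:
                raise ValueError("each streamline needs >= 2 three-dimensional points")
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite streamline coordinates")
            cleaned.append(a)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def total_length(self) -> float:
        return float(sum(np.linalg.norm(np.diff(s, axis=0), axis=1).sum()
                         for s in self.streamlines))

    def subset(self, indices) -> "Tractogram":
        return Tractogram([self.streamlines[i] for i in indices],
                          space=self.space, affine=self.affine)


def connects(streamline: np.ndarray, rois: list[RoiSpec]) -> bool:
    """True iff the streamline has a supporting point inside every listed ROI.

    An empty ROI list is vacuously connected.
    """
    pts = np.asarray(streamline, dtype=float)
    return all(bool(np.any(r.contains(pts))) for r in rois)


def select_combinations(t: Tractogram, rois: list[RoiSpec], min_size: int = 2,
                        max_size: int | None = None) -> dict[tuple[str, ...], set]:
    """Streamline index sets for every connected ROI combination.

    Iterates all size-k ROI subsets (min_size <= k <= max_size) and keeps the
    combinations with at least one connecting streamline. A streamline may
    appear under several combinations. Returned keys are name tuples in the
    input ROI order.
    """
    max_size = len(rois) if max_size is None else max_size
    if not (2 <= min_size <= max_size <= len(rois)):
        raise ValueError("need 2 <= min_size <= max_size <= number of ROIs")

    # precompute per-ROI hit sets once; combination membership is intersection
    hits: dict[str, set] = {}
    for r in rois:
        h = set()
        for i, s in enumerate(t.streamlines):
            if np.any(r.contains(s)):
                h.add(i)
        hits[r.name] = h

    out: dict[tuple[str, ...], set] = {}
    for k in range(min_size, max_size + 1):
        for combo in itertools.combinations(rois, k):
            names = tuple(r.name for r in combo)
            common = set.intersection(*(hits[n] for n in names))
            if common:
                out[names] = common
    return out
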