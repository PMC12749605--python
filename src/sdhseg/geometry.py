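"""Boundary geometry on binary pixel masks.

The boundary loss is defined on *boundary point sets*: the foreground
pixels of a binary mask that touch the background through at least one of
their 8 neighbours (the frame exterior counts as background, so a blob
clipped by the image edge still has a boundary there). Distances between
point sets are exact Euclidean distances in pixel units, with (row, col)
coordinates, 0-based.

Empty sets are handled by saturation: the distance field of an empty
source is the image diagonal everywhere, a finite, maximal, shape-scaled
penalty that keeps the loss defined for all-background predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .exceptions import EmptyTargetSet

__all__ = [
    "BoundaryPointSet",
    "DistanceField",
    "as_binary_mask",
    "diagonal",
    "extract_boundary",
    "min_distances",
    "distance_field",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


def as_binary_mask(mask) -> np.ndarray:
    """Validate and coerce an array-like to a 2-D {0,1} uint8 mask."""
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"mask must be a 2-D grid with H, W >= 1, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask cells must be exactly 0 or 1")
    return arr.astype(np.uint8)


def diagonal(shape: tuple[int, int]) -> float:
    """Image diagonal sqrt(H^2 + W^2), the saturation distance."""
    h, w = shape
    return math.hypot(float(h), float(w))


@dataclass(frozen=True)
class BoundaryPointSet:
    """Ordered, deduplicated integer boundary coordinates of a mask.

    ``points`` is an (n, 2) int array of (row, col) pairs sorted ascending
    in row-major order; ``source_shape`` is the (H, W) of the originating
    grid. The set may be empty.
    """

    points: np.ndarray
    source_shape: tuple[int, int]

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.int64).reshape(-1, 2)
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        pts = np.unique(pts[order], axis=0) if len(pts) else pts
        h, w = self.source_shape
        if len(pts) and (
            pts[:, 0].min() < 0 or pts[:, 0].max() >= h or pts[:, 1].min() < 0 or pts[:, 1].max() >= w
        ):
            raise ValueError("boundary coordinates outside the source grid")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "source_shape", (int(h), int(w)))

    def __len__(self) -> int:
        return len(self.points)

    @property
    def is_empty(self) -> bool:
        return len(self.points) == 0

    def as_mask(self) -> np.ndarray:
        out = np.zeros(self.source_shape, dtype=np.uint8)
        if len(self.points):
            out[self.points[:, 0], self.points[:, 1]] = 1
        return out


@dataclass(frozen=True)
class DistanceField:
    """Exact Euclidean distance (px) from every pixel to a source point set."""

    values: np.ndarray
    source: BoundaryPointSet = field(repr=False)


def extract_boundary(mask) -> BoundaryPointSet:
    """Boundary point set of a binary mask.

    A pixel is a boundary point iff it is foreground and at least one of
    its 8 neighbours is background, with pixels outside the frame counted
    as background. Equivalent to mask minus its binary erosion with a 3x3
    structuring element (erosion not wrapping past the border).
    """
    arr = as_binary_mask(mask)
    eroded = ndimage.binary_erosion(arr, structure=_STRUCT8, border_value=0)
    boundary = arr.astype(bool) & ~eroded
    rows, cols = np.nonzero(boundary)
    return BoundaryPointSet(np.column_stack([rows, cols]), arr.shape)


def min_distances(a: BoundaryPointSet, b: BoundaryPointSet) -> list[tuple[float, int]]:
    """For each point of ``a``, the minimum Euclidean distance into ``b``
    and the index of the attaining point.

    Ties are broken towards the lowest index in ``b``'s sorted order, which
    makes the associated subgradient selection deterministic.
    """
    if b.is_empty:
        raise EmptyTargetSet("cannot take nearest-neighbour distances into an empty set")
    if a.is_empty:
        return []
    d = cdist(a.points.astype(np.float64), b.points.astype(np.float64))
    idx = d.argmin(axis=1)  # argmin returns the first (lowest) index on ties
    return [(float(d[i, j]), int(j)) for i, j in enumerate(idx)]


def distance_field(source: BoundaryPointSet, shape: tuple[int, int]) -> DistanceField:
    """Exact Euclidean distance transform of a point set on a pixel grid.

    An empty source saturates every cell to the image diagonal.
    """
    h, w = shape
    if (int(h), int(w)) != source.source_shape:
        raise ValueError(f"shape {shape} does not match source_shape {source.source_shape}")
    if source.is_empty:
        values = np.full((h, w), diagonal((h, w)), dtype=np.float64)
    else:
        values = ndimage.distance_transform_edt(1 - source.as_mask())
    return DistanceField(values=values, source=source)
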