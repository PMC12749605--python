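"""Shared fixtures and independent oracles.

The brute-force functions here are deliberately naive (pure-python double
loops over point pairs, pixel scans for boundaries) so they stay
independent of the library's vectorised implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from sdhseg.geometry import BoundaryPointSet


# -- independent oracles -------------------------------------------------------


def brute_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """8-neighbour boundary by direct pixel scan (frame exterior = background)."""
    h, w = mask.shape
    pts = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            on_edge = False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if rr < 0 or rr >= h or cc < 0 or cc >= w or not mask[rr, cc]:
                        on_edge = True
            if on_edge:
                pts.append((r, c))
    return pts


def brute_directed_mean(a, b) -> float:
    """Mean over a of the minimum Euclidean distance into b (double loop)."""
    total = 0.0
    for p in a:
        best = math.inf
        for q in b:
            d = math.hypot(p[0] - q[0], p[1] - q[1])
            if d < best:
                best = d
        total += best
    return total / len(a)


def brute_average_hausdorff(a, b, shape) -> float:
    """Bidirectional mean-of-min with the empty-set saturation convention."""
    if not a and not b:
        return 0.0
    if not a or not b:
        return 2.0 * math.hypot(shape[0], shape[1])
    return brute_directed_mean(a, b) + brute_directed_mean(b, a)


def continuous_average_hausdorff(p: np.ndarray, g: np.ndarray) -> float:
    """H(P, G) on real-valued coordinate arrays (for finite differencing)."""
    return (brute_directed_mean([tuple(x) for x in p], [tuple(x) for x in g])
            + brute_directed_mean([tuple(x) for x in g], [tuple(x) for x in p]))


# -- random mask generators ------------------------------------------------------


def random_noise_mask(rng: np.random.Generator, h: int, w: int, density=None) -> np.ndarray:
    density = rng.uniform(0.1, 0.6) if density is None else density
    return (rng.random((h, w)) < density).astype(np.uint8)


def random_blob_mask(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """One or two filled ellipses; moderate boundary size even at 64x64."""
    mask = np.zeros((h, w), dtype=np.uint8)
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(rng.integers(1, 3)):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(1, h / 3), rng.uniform(1, w / 3)
        mask |= (((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0).astype(np.uint8)
    return mask


def points_of(mask: np.ndarray, pts) -> BoundaryPointSet:
    return BoundaryPointSet(np.array(pts, dtype=np.int64).reshape(-1, 2), mask.shape)


# -- fixtures --------------------------------------------------------------------


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small phantom dataset for fast training tests."""
    from sdhseg import generate_dataset

    return generate_dataset(n=24, seed=5, size=(32, 32))
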