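"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-derivations (per-pixel scans,
exhaustive searches, BFS flood fill) kept independent of the library code
they check.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from nmjquant import Calibration


@pytest.fixture
def cal() -> Calibration:
    """Reference confocal calibration: 0.21 µm/px, 0.44 µm z-step."""
    return Calibration(pixel_size_um=0.21, z_step_um=0.44)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_otsu(img: np.ndarray) -> int:
    """Exhaustive between-class-variance scan over all candidate thresholds.

    Candidates are the distinct intensities; class 1 is <= t, class 2 is > t;
    the first maximum wins.
    """
    vals = np.unique(img.ravel())
    n = img.size
    best_t, best_v = None, -1.0
    for t in vals[:-1]:
        low = img <= t
        w1 = low.sum() / n
        w2 = 1.0 - w1
        v = w1 * w2 * (img[low].mean() - img[~low].mean()) ** 2
        if v > best_v:
            best_v, best_t = v, int(t)
    return best_t


def point_in_polygon(point: tuple[float, float], vertices) -> bool:
    """Ray casting with explicit on-segment handling ((row, col) points)."""
    r, c = point
    n = len(vertices)
    # boundary: point on any edge counts as inside
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        cross = (r2 - r1) * (c - c1) - (c2 - c1) * (r - r1)
        if abs(cross) < 1e-9:
            if min(r1, r2) - 1e-9 <= r <= max(r1, r2) + 1e-9 and \
               min(c1, c2) - 1e-9 <= c <= max(c1, c2) + 1e-9:
                return True
    inside = False
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        if (r1 > r) != (r2 > r):
            c_cross = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
            if c < c_cross:
                inside = not inside
    return inside


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """BFS labelling of 8-connected foreground components."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for r0, c0 in zip(*np.nonzero(mask)):
        if seen[r0, c0]:
            continue
        comp = set()
        queue = deque([(int(r0), int(c0))])
        seen[r0, c0] = True
        while queue:
            r, c = queue.popleft()
            comp.add((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] \
                            and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        queue.append((rr, cc))
        comps.append(comp)
    return comps


def is_8_connected(pixels: set[tuple[int, int]]) -> bool:
    """True when the pixel set forms one 8-connected component (BFS)."""
    if not pixels:
        return False
    start = next(iter(pixels))
    seen = {start}
    queue = deque([start])
    while queue:
        r, c = queue.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                nb = (r + dr, c + dc)
                if nb in pixels and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
    return seen == pixels


def digital_disk(radius: float, center=(0, 0)) -> set[tuple[int, int]]:
    """Pixel set of a rasterized disk (centers within radius)."""
    r0, c0 = center
    n = int(np.ceil(radius)) + 1
    return {
        (r0 + i, c0 + j)
        for i in range(-n, n + 1)
        for j in range(-n, n + 1)
        if i * i + j * j <= radius * radius
    }
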