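"""Declustering of fused puncta by seeded deterministic expansion.

Clustered puncta (flagged by the shape criteria) are split at local intensity
maxima: the blurred slice is searched for prominent brightness peaks inside
the punctum, each peak seeds a sub-punctum, and a deterministic multi-source
expansion distributes every pixel of the parent among the seeds. Children are
re-measured and re-classified, and clustered children are split again until
every punctum is single or cannot be split further (fewer than two maxima).

The expansion rule is intentionally bespoke rather than a watershed: for each
already-claimed pixel (in claim order), the eight neighbours are probed in the
fixed order top-left, left, bottom-left, below, bottom-right, right,
top-right, above, interleaving the seeds in ascending label order; the first
seed to probe an unclaimed in-mask pixel claims it. The result is a disjoint
partition of the parent that is independent of the execution environment.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .image_model import Calibration
from .preprocess import CONNECTIVITY_8, gaussian_blur
from .puncta import ClusterCriteria, Punctum, PunctumStatus, make_punctum

logger = logging.getLogger("nmjquant")

# expansion probe order: top-left, left, bottom-left, below, bottom-right,
# right, top-right, above — (drow, dcol) in image coordinates
EXPANSION_DIRECTIONS = (
    (-1, -1),
    (0, -1),
    (1, -1),
    (1, 0),
    (1, 1),
    (0, 1),
    (-1, 1),
    (-1, 0),
)


@dataclass(frozen=True)
class MaximaSeed:
    """One expansion nucleus: a local-maximum position with a unique label."""

    position: tuple[int, int]
    label: int


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the declustering stage.

    gaussian_sigma:
        Blur applied to the raw slice before maxima detection (pixels).
    maxima_prominence:
        Noise tolerance for peak detection, in intensity units. ``None``
        (default) uses 10% of the slice's dynamic range, which is robust
        across bit depths.
    max_rounds:
        Safety cap on recursive splitting depth per lineage.
    """

    gaussian_sigma: float = 1.0
    maxima_prominence: float | None = None
    max_rounds: int = 10

    def __post_init__(self) -> None:
        if self.maxima_prominence is not None and self.maxima_prominence < 0:
            raise ValueError("maxima_prominence must be >= 0")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


def _pixel_components(pixels: set[tuple[int, int]]) -> list[set[tuple[int, int]]]:
    """Split a pixel set into its 8-connected components."""
    coords = np.array(sorted(pixels))
    offset = coords.min(axis=0)
    local = np.zeros(coords.max(axis=0) - offset + 1, dtype=bool)
    local[tuple((coords - offset).T)] = True
    labels, n = ndimage.label(local, structure=CONNECTIVITY_8)
    comps = []
    for i in range(1, n + 1):
        rr, cc = np.nonzero(labels == i)
        comps.append(
            {(int(r + offset[0]), int(c + offset[1])) for r, c in zip(rr, cc)}
        )
    return comps


def find_local_maxima(
    slice_: np.ndarray, punctum: Punctum, params: SegmentationParams = SegmentationParams()
) -> list[MaximaSeed]:
    """Detect prominent local brightness maxima inside one punctum.

    The slice is expected to be already blurred with ``params.gaussian_sigma``.
    A candidate is a pixel (or plateau of equal-valued pixels) whose value is
    not exceeded by any 8-neighbour within the punctum; each plateau yields
    one candidate at its centroid-nearest pixel. Candidates are then filtered
    by prominence: walking candidates in decreasing brightness, a peak
    suppresses every not-brighter candidate reachable from it through pixels
    above ``peak - prominence``. Labels are assigned 1..k in decreasing peak
    brightness (ties broken by position).
    """
    img = np.asarray(slice_, dtype=np.float64)
    prominence = params.maxima_prominence
    if prominence is None:
        prominence = 0.10 * float(img.max() - img.min())

    coords = np.array(sorted(punctum.pixels))
    offset = coords.min(axis=0)
    shape = coords.max(axis=0) - offset + 1
    inside = np.zeros(shape, dtype=bool)
    inside[tuple((coords - offset).T)] = True
    values = np.full(shape, -np.inf)
    values[inside] = img[coords[:, 0], coords[:, 1]]

    padded = np.full((shape[0] + 2, shape[1] + 2), -np.inf)
    padded[1:-1, 1:-1] = values
    neigh_max = np.full(shape, -np.inf)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            shifted = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
            neigh_max = np.maximum(neigh_max, shifted)
    is_candidate = inside & (values >= neigh_max)

    # group equal-valued adjacent candidates into plateaus
    plateau_labels, n_plateaus = ndimage.label(is_candidate, structure=CONNECTIVITY_8)
    candidates: list[tuple[float, tuple[int, int]]] = []  # (peak value, representative)
    for i in range(1, n_plateaus + 1):
        rr, cc = np.nonzero(plateau_labels == i)
        centroid = (rr.mean(), cc.mean())
        dist2 = (rr - centroid[0]) ** 2 + (cc - centroid[1]) ** 2
        order = np.lexsort((cc, rr, dist2))
        rep_local = (int(rr[order[0]]), int(cc[order[0]]))
        candidates.append((float(values[rep_local]), rep_local))

    candidates.sort(key=lambda vc: (-vc[0], vc[1]))
    suppressed: set[tuple[int, int]] = set()
    accepted: list[tuple[int, int]] = []
    for value, pos in candidates:
        if pos in suppressed:
            continue
        accepted.append(pos)
        # flood the region reachable above (peak - prominence); any
        # not-brighter candidate inside it belongs to this peak
        reach = inside & (values > value - prominence)
        flood_labels, _ = ndimage.label(reach, structure=CONNECTIVITY_8)
        region_id = flood_labels[pos]
        for other_value, other_pos in candidates:
            if other_pos != pos and other_value <= value and flood_labels[other_pos] == region_id:
                suppressed.add(other_pos)

    return [
        MaximaSeed(position=(int(r + offset[0]), int(c + offset[1])), label=i + 1)
        for i, (r, c) in enumerate(accepted)
    ]


def expand_seeds(
    punctum_mask: frozenset[tuple[int, int]] | set,
    seeds: list[MaximaSeed],
) -> dict[int, set[tuple[int, int]]]:
    """Partition a punctum's pixels among seeds by deterministic expansion.

    Each seed keeps an ordered list of claimed pixels (the seed itself is
    pixel 0). Expansion proceeds over the claimed-pixel index; at each index,
    for each probe direction in the fixed order, for each seed in ascending
    label order, the neighbour of that seed's pixel at that index is claimed
    iff it lies inside the punctum and is still unclaimed. The loop ends when
    every pixel of the punctum is claimed. Regions are disjoint, cover the
    punctum exactly, are 8-connected, and each contains its seed.
    """
    mask = {(int(r), int(c)) for r, c in punctum_mask}
    if not seeds:
        raise ValueError("at least one seed required")
    labels = sorted(s.label for s in seeds)
    if len(set(labels)) != len(labels):
        raise ValueError("seed labels must be unique")
    for s in seeds:
        if tuple(s.position) not in mask:
            raise ValueError(f"seed {s.label} at {s.position} lies outside the punctum")
    positions = {s.label: tuple(s.position) for s in seeds}
    if len({positions[l] for l in labels}) != len(labels):
        raise ValueError("seed positions must be distinct")

    claimed: dict[int, list[tuple[int, int]]] = {l: [positions[l]] for l in labels}
    owner: dict[tuple[int, int], int] = {positions[l]: l for l in labels}
    index = 0
    while len(owner) < len(mask):
        if index > len(mask):
            raise RuntimeError(
                "expansion stalled: punctum pixels unreachable (mask not 8-connected?)"
            )
        for dr, dc in EXPANSION_DIRECTIONS:
            for label in labels:
                pixels = claimed[label]
                if index >= len(pixels):
                    continue
                r, c = pixels[index]
                nb = (r + dr, c + dc)
                if nb in mask and nb not in owner:
                    owner[nb] = label
                    pixels.append(nb)
        index += 1
    return {l: set(px) for l, px in claimed.items()}


def segment_all(
    puncta: list[Punctum],
    slice_: np.ndarray,
    criteria: ClusterCriteria = ClusterCriteria(),
    params: SegmentationParams = SegmentationParams(),
    cal: Calibration = Calibration(),
) -> list[Punctum]:
    """Recursively split clustered puncta until all are single or unsplittable.

    Worklist semantics: single puncta pass through untouched; a clustered
    punctum with at least two prominent maxima is replaced by its expansion
    sub-puncta, which are re-measured, re-classified and re-enqueued; a
    clustered punctum with fewer than two maxima (or one whose lineage hit
    ``max_rounds``) is retained with status ``unsegmentable``. Pixels are
    conserved exactly: the union of output pixel sets equals the input union.
    """
    blurred = gaussian_blur(slice_, params.gaussian_sigma)
    next_id = max((p.id for p in puncta), default=-1) + 1
    work: deque[tuple[Punctum, int]] = deque((p, 0) for p in puncta)
    out: list[Punctum] = []
    while work:
        p, depth = work.popleft()
        if p.status is not PunctumStatus.CLUSTERED:
            out.append(p)
            continue
        if depth >= params.max_rounds:
            logger.warning(
                "punctum %s: recursion cap (%d rounds) reached; marking unsegmentable",
                p.id,
                params.max_rounds,
            )
            out.append(replace(p, status=PunctumStatus.UNSEGMENTABLE))
            continue
        seeds = find_local_maxima(blurred, p, params)
        if len(seeds) < 2:
            out.append(replace(p, status=PunctumStatus.UNSEGMENTABLE))
            continue
        partition = expand_seeds(p.pixels, seeds)
        for label in sorted(partition):
            # defensive connectivity repair: the specced order cannot produce
            # a disconnected region, but a broken region is split, not dropped
            for comp in _pixel_components(partition[label]):
                child = make_punctum(
                    comp,
                    cal,
                    punctum_id=next_id,
                    criteria=criteria,
                    clipped_by_roi=p.clipped_by_roi,
                    channel=p.channel,
                    slice_index=p.slice_index,
                    roi_name=p.roi_name,
                )
                next_id += 1
                work.append((child, depth + 1))
    return out
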