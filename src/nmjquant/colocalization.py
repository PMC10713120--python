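"""Object-based co-localization between the two channels.

For each punctum the fraction of its area covered by the other channel's
foreground (the pixel-wise AND of the two binary masks, restricted to the
punctum) decides whether it counts as co-localized. Rather than fixing one
cutoff, counts are tallied at 11 progressively stricter thresholds:
>0%, >10%, ..., >90%, and =100% (entire area covered). Both directions —
channel 1 against channel 2 and vice versa — are tabulated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .image_model import BinaryMask
from .puncta import Punctum

#: The 11 overlap thresholds, in percent. All but the last are strict
#: lower bounds (fraction > t/100); 100 requires exact full coverage.
THRESHOLDS: tuple[int, ...] = tuple(range(0, 101, 10))


def threshold_label(t: int) -> str:
    """Stable column label for a threshold (``gt_30`` for >30%, ``eq_100``)."""
    return "eq_100" if t == 100 else f"gt_{t}"


def is_colocalized(overlap_fraction: float, threshold_pct: int) -> bool:
    """Apply one threshold: strict ``>`` below 100%, exact equality at 100%."""
    if threshold_pct == 100:
        return overlap_fraction == 1.0
    return overlap_fraction > threshold_pct / 100.0


@dataclass(frozen=True)
class OverlapRecord:
    """Fractional overlap of one punctum with the other channel's foreground."""

    punctum_id: int
    channel: int
    slice_index: int
    overlap_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError(f"overlap_fraction must be in [0, 1], got {self.overlap_fraction}")


def overlap_image(mask1: BinaryMask, mask2: BinaryMask) -> BinaryMask:
    """Pixel-wise Boolean AND of two same-shape masks."""
    if mask1.shape != mask2.shape:
        raise ValueError(f"shape mismatch: {mask1.shape} vs {mask2.shape}")
    return BinaryMask(mask1.data & mask2.data, provenance=mask1.provenance)


def punctum_overlap_fraction(p: Punctum, other_mask: BinaryMask) -> float:
    """Fraction of the punctum's pixels covered by the other channel's mask."""
    if len(p.pixels) == 0:
        raise ValueError("empty punctum")
    rows, cols = other_mask.shape
    covered = 0
    for r, c in p.pixels:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"punctum pixel {(r, c)} outside mask shape {(rows, cols)}")
        if other_mask.data[r, c]:
            covered += 1
    return covered / len(p.pixels)


@dataclass
class ColocTable:
    """Per-ROI tally of total/single/co-localized puncta per channel.

    ``counts[channel][t]`` is a ``(single, coloc)`` pair for threshold ``t``;
    for every channel and threshold ``single + coloc == totals[channel]``.
    """

    roi_name: str
    totals: dict[int, int] = field(default_factory=dict)
    counts: dict[int, dict[int, tuple[int, int]]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per channel, single/coloc columns per threshold.

        Columns: ``roi``, ``channel``, ``total``, then ``single_<lbl>`` and
        ``coloc_<lbl>`` for each threshold label (``gt_0`` ... ``gt_90``,
        ``eq_100``).
        """
        rows = []
        for channel in sorted(self.totals):
            row: dict[str, object] = {
                "roi": self.roi_name,
                "channel": channel,
                "total": self.totals[channel],
            }
            for t in THRESHOLDS:
                single, coloc = self.counts[channel][t]
                row[f"single_{threshold_label(t)}"] = single
                row[f"coloc_{threshold_label(t)}"] = coloc
            rows.append(row)
        return pd.DataFrame(rows)


def tabulate(
    records: Iterable[OverlapRecord],
    roi_name: str,
    channels: Sequence[int] = (1, 2),
) -> ColocTable:
    """Tally single/co-localized puncta at all 11 thresholds per channel.

    Counts accumulate over every slice of the ROI; a physical punctum visible
    on several z-slices contributes once per slice, matching the per-slice
    tally of the workflow this package reproduces.
    """
    table = ColocTable(roi_name=roi_name)
    records = list(records)
    for channel in channels:
        fractions = np.array(
            [r.overlap_fraction for r in records if r.channel == channel], dtype=float
        )
        total = len(fractions)
        table.totals[channel] = total
        table.counts[channel] = {}
        for t in THRESHOLDS:
            if t == 100:
                coloc = int((fractions == 1.0).sum())
            else:
                coloc = int((fractions > t / 100.0).sum())
            table.counts[channel][t] = (total - coloc, coloc)
    return table
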