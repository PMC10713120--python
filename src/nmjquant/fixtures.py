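"""Synthetic calibrated two-channel z-stacks with known ground truth.

Every pipeline stage is testable without microscopy data: the generator
renders Gaussian (or exact axis-aligned rectangular) spots on a dark
background, optionally fuses groups of spots into single connected
components, plans exact cross-channel overlap fractions, adds Gaussian
read-out noise, and writes a calibrated TIFF plus a JSON ground-truth
sidecar. Generation is bit-reproducible from (parameters, seed).

Geometry: spots are placed on a coarse grid of non-overlapping cells so
that unrelated spots can never merge. Rectangular spots are 5×10 px, so a
planned overlap fraction must be a multiple of 0.1 (exact pixel counts by
construction). Gaussian spots (default sigma 3 px, peak 180 over a
background of 8) are sized so an isolated spot is classified single under
the default shape criteria, while a fused pair exceeds the 4 µm² area cap
and is declustered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .image_model import Calibration, RoiRegion, ZStack, write_rois, write_stack

CELL = 32  # placement grid pitch (px); one spot group per cell
RECT_SHAPE = (5, 10)  # rows × cols of an exact rectangular punctum
FUSION_SEPARATION = 10  # px between fused Gaussian spot centers


@dataclass(frozen=True)
class SpotSpec:
    """One rendered spot: position, brightness profile and channel."""

    row: float
    col: float
    slice_index: int
    channel: int  # 1 or 2
    peak_intensity: float = 180.0
    sigma_px: tuple[float, float] = (3.0, 3.0)  # (row, col) widths; Gaussian only
    kind: str = "gaussian"  # "gaussian" | "rect"


@dataclass
class GroundTruth:
    """Everything a test needs to verify a generated stack."""

    spots: list[SpotSpec] = field(default_factory=list)
    fusion_groups: list[list[int]] = field(default_factory=list)  # indices into spots
    overlap_plan: list[float] = field(default_factory=list)  # per channel-1 spot
    frame_shape: tuple[int, int] = (128, 128)
    n_slices: int = 3
    noise_sd: float = 0.0
    background: float = 8.0
    seed: int = 0
    pixel_size_um: float = 0.21

    def spot_indices(self, channel: int) -> list[int]:
        return [i for i, s in enumerate(self.spots) if s.channel == channel]

    def expected_components(self, channel: int) -> int:
        """Connected components expected before declustering."""
        n = len(self.spot_indices(channel))
        if channel == 1:
            for group in self.fusion_groups:
                n -= len(group) - 1
        return n

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spots": [asdict(s) for s in self.spots],
            "fusion_groups": self.fusion_groups,
            "overlap_plan": self.overlap_plan,
            "frame_shape": list(self.frame_shape),
            "n_slices": self.n_slices,
            "noise_sd": self.noise_sd,
            "background": self.background,
            "seed": self.seed,
            "pixel_size_um": self.pixel_size_um,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        spots = [
            SpotSpec(**{**s, "sigma_px": tuple(s["sigma_px"])}) for s in raw.pop("spots")
        ]
        raw["frame_shape"] = tuple(raw["frame_shape"])
        return cls(spots=spots, **raw)


def full_frame_roi(frame_shape: tuple[int, int], name: str = "hemisomite_1") -> RoiRegion:
    """Rectangular ROI covering the whole frame (boundary pixels included)."""
    rows, cols = frame_shape
    return RoiRegion(
        name, [(0, 0), (0, cols - 1), (rows - 1, cols - 1), (rows - 1, 0)]
    )


def rect_pixels(row: float, col: float, shape: tuple[int, int] = RECT_SHAPE) -> set[tuple[int, int]]:
    """Pixel set of a rectangular spot centered at (row, col)."""
    h, w = shape
    r0, c0 = int(round(row)) - h // 2, int(round(col)) - w // 2
    return {(r0 + i, c0 + j) for i in range(h) for j in range(w)}


def render_spots(
    spots: list[SpotSpec],
    frame_shape: tuple[int, int],
    n_slices: int,
    n_channels: int = 2,
    background: float = 8.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    pixel_size_um: float = 0.21,
) -> ZStack:
    """Render spot specs into a calibrated 8-bit two-channel stack."""
    rows, cols = frame_shape
    img = np.full((n_channels, n_slices, rows, cols), background, dtype=np.float64)
    rr, cc = np.mgrid[0:rows, 0:cols]
    for s in spots:
        plane = img[s.channel - 1, s.slice_index]
        if s.kind == "rect":
            for r, c in rect_pixels(s.row, s.col):
                if 0 <= r < rows and 0 <= c < cols:
                    plane[r, c] += s.peak_intensity
        else:
            sr, sc = s.sigma_px
            plane += s.peak_intensity * np.exp(
                -((rr - s.row) ** 2 / (2 * sr**2) + (cc - s.col) ** 2 / (2 * sc**2))
            )
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img += rng.normal(0.0, noise_sd, size=img.shape)
    data = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ZStack(
        data=data,
        calibration=Calibration(pixel_size_um=pixel_size_um),
        channel_names=("SV2a", "aBTX"),
    )


def _cell_centers(frame_shape: tuple[int, int], n_slices: int) -> list[tuple[int, int, int]]:
    rows, cols = frame_shape
    centers = []
    for s in range(n_slices):
        for gr in range(rows // CELL):
            for gc in range(cols // CELL):
                centers.append((s, gr * CELL + CELL // 2, gc * CELL + CELL // 2))
    return centers


def make_stack(
    n_spots_per_channel: int,
    overlap_plan: list[float] | None = None,
    fusion_pairs: list[tuple[int, ...]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    spot_kind: str = "gaussian",
    frame_shape: tuple[int, int] = (128, 128),
    n_slices: int = 3,
    pixel_size_um: float = 0.21,
    background: float = 8.0,
    peak_intensity: float = 180.0,
    sigma_px: float = 3.0,
    out_path: str | Path | None = None,
) -> tuple[ZStack, GroundTruth]:
    """Generate a two-channel stack with a fully known spot plan.

    ``overlap_plan`` gives, per channel-1 spot, the planned fraction of its
    area covered by a paired channel-2 spot: 0 places the partner in its own
    far-away cell; with rectangular spots the fraction is realized exactly
    (it must be a multiple of 0.1), with Gaussian spots a positive fraction
    places the partner at the same center (near-total overlap).
    ``fusion_pairs`` lists groups of channel-1 spot indices rendered close
    enough to merge into one connected component. Raises when the plan does
    not fit the frame geometry. Writes a calibrated TIFF and a JSON sidecar
    next to it when ``out_path`` is given.
    """
    n = n_spots_per_channel
    if overlap_plan is None:
        overlap_plan = [0.0] * n
    if len(overlap_plan) != n:
        raise ValueError("overlap_plan must have one fraction per channel-1 spot")
    for f in overlap_plan:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"overlap fraction {f} outside [0, 1]")
        if spot_kind == "rect" and abs(f * RECT_SHAPE[1] - round(f * RECT_SHAPE[1])) > 1e-9:
            raise ValueError(
                f"overlap fraction {f} not realizable exactly with {RECT_SHAPE} rectangles"
            )
    fusion_groups = [sorted(g) for g in (fusion_pairs or [])]
    fused = [i for g in fusion_groups for i in g]
    if len(set(fused)) != len(fused):
        raise ValueError("fusion groups must be disjoint")
    if any(i >= n or i < 0 for i in fused):
        raise ValueError("fusion index out of range")

    rng = np.random.default_rng(seed)
    # one cell per channel-1 group and per unpaired channel-2 spot
    grouped = {i: g for g in fusion_groups for i in g}
    ch1_groups: list[list[int]] = []
    seen: set[int] = set()
    for i in range(n):
        if i in seen:
            continue
        g = grouped.get(i, [i])
        ch1_groups.append(list(g))
        seen.update(g)
    n_unpaired_ch2 = sum(1 for f in overlap_plan if f == 0.0)
    cells = _cell_centers(frame_shape, n_slices)
    needed = len(ch1_groups) + n_unpaired_ch2
    if needed > len(cells):
        raise ValueError(
            f"plan needs {needed} placement cells; frame provides {len(cells)}"
        )
    order = rng.permutation(len(cells))
    cell_iter = iter(order)

    spots: list[SpotSpec] = [None] * (2 * n)  # type: ignore[list-item]
    sig = (float(sigma_px), float(sigma_px))
    kind = spot_kind
    jitter = 0 if kind == "rect" else 3

    def place_ch1(group: list[int]) -> None:
        s, r, c = cells[next(cell_iter)]
        if jitter:
            r += int(rng.integers(-jitter, jitter + 1))
            c += int(rng.integers(-jitter, jitter + 1))
        k = len(group)
        for j, idx in enumerate(group):
            cc = c + (j - (k - 1) / 2.0) * FUSION_SEPARATION
            spots[idx] = SpotSpec(
                row=float(r), col=float(cc), slice_index=s, channel=1,
                peak_intensity=peak_intensity, sigma_px=sig, kind=kind,
            )

    for group in ch1_groups:
        place_ch1(group)
    for i in range(n):
        f = overlap_plan[i]
        partner = spots[i]
        if f > 0.0:
            if kind == "rect":
                shift = RECT_SHAPE[1] - int(round(f * RECT_SHAPE[1]))
            else:
                shift = 0
            spots[n + i] = SpotSpec(
                row=partner.row, col=partner.col + shift, slice_index=partner.slice_index,
                channel=2, peak_intensity=peak_intensity, sigma_px=sig, kind=kind,
            )
        else:
            s, r, c = cells[next(cell_iter)]
            if jitter:
                r += int(rng.integers(-jitter, jitter + 1))
                c += int(rng.integers(-jitter, jitter + 1))
            spots[n + i] = SpotSpec(
                row=float(r), col=float(c), slice_index=s, channel=2,
                peak_intensity=peak_intensity, sigma_px=sig, kind=kind,
            )

    stack = render_spots(
        spots, frame_shape, n_slices,
        background=background, noise_sd=noise_sd, rng=rng,
        pixel_size_um=pixel_size_um,
    )
    truth = GroundTruth(
        spots=spots,
        fusion_groups=fusion_groups,
        overlap_plan=list(overlap_plan),
        frame_shape=frame_shape,
        n_slices=n_slices,
        noise_sd=noise_sd,
        background=background,
        seed=seed,
        pixel_size_um=pixel_size_um,
    )
    if out_path is not None:
        out_path = Path(out_path)
        write_stack(stack, out_path)
        truth.to_json(out_path.with_suffix(".truth.json"))
    return stack, truth


#: Study conditions for the qualitative disease-contrast fixture: a healthy
#: ("WT-like") group and a depleted group with ~28% fewer spots per channel
#: and a lower pairing (co-localization) rate, echoing presynaptic loss in a
#: motor-neuron-disease model.
WT_MEAN_SPOTS = 30.0
DEPLETED_MEAN_SPOTS = 21.5
WT_PAIRED_FRACTION = 0.40
DEPLETED_PAIRED_FRACTION = 0.25
CONTRAST_FRAME = (256, 256)
#: One densely populated optical section per stack: real hemisomite slices
#: always carry tens of puncta, and Otsu thresholding presumes signal is
#: present; a slice with no spots at all would binarize pure noise.
CONTRAST_N_SLICES = 1
CONTRAST_NOISE_SD = 4.0
_MAX_SPOTS = 36  # placement-capacity clamp for one contrast slice


def make_disease_contrast(
    seed: int,
    n_stacks_per_group: int = 10,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[ZStack, GroundTruth]], list[tuple[ZStack, GroundTruth]]]:
    """Two seeded stack sets emulating a healthy-vs-depleted group contrast.

    Spot counts per stack are Poisson-distributed around the group means and
    the depleted group plans fewer cross-channel overlaps, so group means of
    total and co-localized puncta order as depleted < WT. When ``out_dir`` is
    given, stacks are written under ``wt/`` and ``depleted/`` subfolders with
    a shared full-frame ROI file in each.
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, list[tuple[ZStack, GroundTruth]]] = {"wt": [], "depleted": []}
    specs = {
        "wt": (WT_MEAN_SPOTS, WT_PAIRED_FRACTION),
        "depleted": (DEPLETED_MEAN_SPOTS, DEPLETED_PAIRED_FRACTION),
    }
    for label, (mean_spots, paired_fraction) in specs.items():
        for _ in range(n_stacks_per_group):
            n = int(min(max(rng.poisson(mean_spots), 1), _MAX_SPOTS))
            n_paired = int(round(paired_fraction * n))
            plan = [1.0] * n_paired + [0.0] * (n - n_paired)
            stack_seed = int(rng.integers(0, 2**31 - 1))
            groups[label].append(
                make_stack(
                    n,
                    overlap_plan=plan,
                    noise_sd=CONTRAST_NOISE_SD,
                    seed=stack_seed,
                    frame_shape=CONTRAST_FRAME,
                    n_slices=CONTRAST_N_SLICES,
                )
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        for label, stacks in groups.items():
            sub = out_dir / label
            sub.mkdir(parents=True, exist_ok=True)
            for i, (stack, truth) in enumerate(stacks):
                write_stack(stack, sub / f"{label}_{i:02d}.tif")
                truth.to_json(sub / f"{label}_{i:02d}.truth.json")
            write_rois([full_frame_roi(CONTRAST_FRAME)], sub / "rois.json")
    return groups["wt"], groups["depleted"]
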