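"""End-to-end orchestration: stacks in, co-localization tables out.

For every TIFF stack in the input folder and every ROI (hemisomite), every
slice of every channel is conditioned (blur → contrast stretch → Otsu →
despeckle), puncta are detected and optionally declustered, and per-punctum
overlap fractions against the other channel feed the per-ROI tally table.
The whole pipeline is deterministic: two runs on identical inputs and
configuration produce byte-identical CSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .colocalization import BinaryMask, ColocTable, OverlapRecord, tabulate
from .image_model import RoiRegion, ZStack, rasterize_roi, read_rois, read_stack
from .preprocess import PreprocessParams, preprocess_slice
from .puncta import ClusterCriteria, Punctum, PunctumStatus, find_puncta
from .segmentation import SegmentationParams, segment_all

logger = logging.getLogger("nmjquant")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run bit-exactly."""

    input_dir: str | Path = "."
    roi_file: str | Path | None = None
    output_dir: str | Path = "results"
    pixel_size_um: float | None = None  # None: TIFF tags, then 0.21 default
    channel_names: tuple[str, str] = ("SV2a", "aBTX")  # 1 = presynaptic
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    criteria: dict[int, ClusterCriteria] = field(
        default_factory=lambda: {1: ClusterCriteria(), 2: ClusterCriteria()}
    )
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    segmentation_enabled: bool = True
    exclude_unsegmentable: bool = False
    projection: str = "max"  # z-projection method: max | mean
    save_masks: bool = False

    def echo(self) -> dict:
        """Flat, JSON-serializable parameter echo for the run report."""
        return {
            "input_dir": str(self.input_dir),
            "roi_file": str(self.roi_file),
            "output_dir": str(self.output_dir),
            "pixel_size_um": self.pixel_size_um,
            "channel_names": list(self.channel_names),
            "preprocess": asdict(self.preprocess),
            "criteria": {ch: asdict(c) for ch, c in self.criteria.items()},
            "segmentation": asdict(self.segmentation),
            "segmentation_enabled": self.segmentation_enabled,
            "exclude_unsegmentable": self.exclude_unsegmentable,
            "projection": self.projection,
            "save_masks": self.save_masks,
        }


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file mirroring the CLI flags."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    for key in ("input_dir", "roi_file", "output_dir", "pixel_size_um",
                "segmentation_enabled", "exclude_unsegmentable", "projection",
                "save_masks"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "channel_names" in raw:
        cfg.channel_names = tuple(raw["channel_names"])
    if "preprocess" in raw:
        cfg.preprocess = PreprocessParams(**raw["preprocess"])
    if "segmentation" in raw:
        cfg.segmentation = SegmentationParams(**raw["segmentation"])
    if "criteria" in raw:
        crit = raw["criteria"]
        if isinstance(crit, dict) and all(isinstance(v, dict) for v in crit.values()):
            cfg.criteria = {int(ch): ClusterCriteria(**v) for ch, v in crit.items()}
        else:  # one set of thresholds for both channels
            cfg.criteria = {1: ClusterCriteria(**crit), 2: ClusterCriteria(**crit)}
    return cfg


@dataclass
class StageCounts:
    """Per-ROI, per-channel punctum bookkeeping across pipeline stages.

    Invariants: detected == singles + clustered and
    clustered == segmented_parents + unsegmentable_parents.
    """

    detected: int = 0
    singles: int = 0
    clustered: int = 0
    segmented_parents: int = 0
    unsegmentable_parents: int = 0
    final_total: int = 0


@dataclass
class ImageResult:
    name: str
    tables: dict[str, ColocTable] = field(default_factory=dict)
    stage_counts: dict[tuple[str, int], StageCounts] = field(default_factory=dict)
    error: str | None = None


@dataclass
class RunReport:
    images: dict[str, ImageResult] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def z_project(stack: ZStack, channel: int, method: str = "max") -> np.ndarray:
    """Project one channel along z (``max`` or ``mean`` of each pixel)."""
    if not 0 <= channel < stack.n_channels:
        raise ValueError(f"channel {channel} out of range")
    data = stack.data[channel]
    if method == "max":
        return data.max(axis=0)
    if method == "mean":
        return data.mean(axis=0)
    raise ValueError(f"unknown projection method '{method}'")


def analyse_stack(
    stack: ZStack,
    rois: list[RoiRegion],
    config: RunConfig,
    name: str = "stack",
) -> ImageResult:
    """Run detection, declustering and co-localization on one stack.

    Returns per-ROI tally tables and stage counts; the stack must have
    exactly two channels.
    """
    if stack.n_channels != 2:
        raise ValueError(f"pipeline requires exactly 2 channels, got {stack.n_channels}")
    result = ImageResult(name=name)
    cal = stack.calibration
    out_max = float(stack.bit_depth_max)
    for roi in rois:
        roi_mask = rasterize_roi(roi, stack.frame_shape).data
        counts = {1: StageCounts(), 2: StageCounts()}
        # final puncta and foreground per (channel, slice)
        final: dict[tuple[int, int], list[Punctum]] = {}
        foreground: dict[tuple[int, int], np.ndarray] = {}
        for s in range(stack.n_slices):
            for ch in (1, 2):
                mask, _ = preprocess_slice(
                    stack.data[ch - 1, s],
                    cal,
                    config.preprocess,
                    out_max=out_max,
                    roi_mask=roi_mask,
                    provenance=(ch, s, roi.name),
                )
                criteria = config.criteria[ch]
                puncta = find_puncta(mask, cal, criteria, roi_mask=roi_mask)
                sc = counts[ch]
                sc.detected += len(puncta)
                sc.singles += sum(p.status is PunctumStatus.SINGLE for p in puncta)
                sc.clustered += sum(p.status is PunctumStatus.CLUSTERED for p in puncta)
                if config.segmentation_enabled:
                    processed: list[Punctum] = []
                    for p in puncta:
                        if p.status is not PunctumStatus.CLUSTERED:
                            processed.append(p)
                            continue
                        pieces = segment_all(
                            [p], stack.data[ch - 1, s], criteria, config.segmentation, cal
                        )
                        if len(pieces) == 1 and pieces[0].status is PunctumStatus.UNSEGMENTABLE:
                            sc.unsegmentable_parents += 1
                        else:
                            sc.segmented_parents += 1
                        processed.extend(pieces)
                    puncta = processed
                if config.exclude_unsegmentable:
                    puncta = [p for p in puncta if p.status is not PunctumStatus.UNSEGMENTABLE]
                sc.final_total += len(puncta)
                final[(ch, s)] = puncta
                fg = np.zeros(stack.frame_shape, dtype=bool)
                for p in puncta:
                    rows, cols = zip(*p.pixels)
                    fg[list(rows), list(cols)] = True
                foreground[(ch, s)] = fg
        records: list[OverlapRecord] = []
        for s in range(stack.n_slices):
            for ch, other in ((1, 2), (2, 1)):
                other_fg = BinaryMask(foreground[(other, s)])
                for p in final[(ch, s)]:
                    covered = sum(other_fg.data[r, c] for r, c in p.pixels)
                    records.append(
                        OverlapRecord(
                            punctum_id=p.id,
                            channel=ch,
                            slice_index=s,
                            overlap_fraction=covered / len(p.pixels),
                        )
                    )
        result.tables[roi.name] = tabulate(records, roi.name)
        result.stage_counts[(roi.name, 1)] = counts[1]
        result.stage_counts[(roi.name, 2)] = counts[2]
    return result


def result_frame(result: ImageResult) -> pd.DataFrame:
    """Stack the per-ROI tally tables of one image into a single DataFrame."""
    frames = [result.tables[roi].to_frame() for roi in sorted(result.tables)]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_pipeline(config: RunConfig) -> RunReport:
    """Process every TIFF stack in ``config.input_dir`` and write CSV tables.

    Files are visited in lexicographic order. A file that fails (unreadable
    TIFF, wrong channel count, ROI outside the frame) is recorded in the
    report and the run continues. One CSV per image is written to
    ``config.output_dir`` as ``<stem>_coloc.csv``.
    """
    report = RunReport(params=config.echo())
    input_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.roi_file is None:
        raise ValueError("a ROI file is required")
    rois = read_rois(config.roi_file)
    tiffs = sorted(p for p in input_dir.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
    for path in tiffs:
        try:
            stack = read_stack(
                path,
                pixel_size_um=config.pixel_size_um,
                channel_names=config.channel_names,
            )
            result = analyse_stack(stack, rois, config, name=path.stem)
        except Exception as exc:  # keep batch alive; record per-file failure
            logger.error("%s: %s", path.name, exc)
            report.images[path.stem] = ImageResult(name=path.stem, error=str(exc))
            continue
        report.images[path.stem] = result
        frame = result_frame(result)
        frame.to_csv(out_dir / f"{path.stem}_coloc.csv", index=False)
        if config.save_masks:
            _save_masks(stack, rois, config, out_dir / f"{path.stem}_masks.tif")
    return report


def _save_masks(stack: ZStack, rois: list[RoiRegion], config: RunConfig, path: Path) -> None:
    """Write the despeckled foreground of every channel/slice as a QC TIFF."""
    import tifffile

    union_roi = np.zeros(stack.frame_shape, dtype=bool)
    for roi in rois:
        union_roi |= rasterize_roi(roi, stack.frame_shape).data
    out = np.zeros(stack.data.shape, dtype=np.uint8)
    for ch in range(stack.n_channels):
        for s in range(stack.n_slices):
            mask, _ = preprocess_slice(
                stack.data[ch, s],
                stack.calibration,
                config.preprocess,
                out_max=float(stack.bit_depth_max),
                roi_mask=union_roi,
            )
            out[ch, s] = mask.data.astype(np.uint8) * 255
    tifffile.imwrite(str(path), np.moveaxis(out, 0, 1), imagej=True, metadata={"axes": "ZCYX"})
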