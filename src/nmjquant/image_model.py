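"""Calibrated image and geometry types shared by all pipeline stages.

Conventions used throughout the package:

* coordinates are ``(row, column)``, 0-based, with pixel centers at integer
  coordinates;
* a pixel belongs to a polygonal region of interest (ROI) if its center lies
  inside or on the boundary of the polygon;
* image volumes are indexed ``(channel, slice, row, column)``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
import tifffile

logger = logging.getLogger("nmjquant")

#: Pixel edge length (µm) of the reference confocal acquisition, used when
#: neither an explicit configuration value nor TIFF resolution tags are found.
DEFAULT_PIXEL_SIZE_UM = 0.21
#: Reference spacing between z-slices (µm); informational only.
DEFAULT_Z_STEP_UM = 0.44


@dataclass(frozen=True)
class Calibration:
    """Spatial calibration of an image volume.

    Parameters
    ----------
    pixel_size_um:
        Edge length of one pixel in micrometres. Must be positive.
    z_step_um:
        Spacing between consecutive z-slices in micrometres. Carried for
        provenance; no operation in the pipeline measures across slices.
    """

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.z_step_um > 0:
            raise ValueError(f"z_step_um must be > 0, got {self.z_step_um}")

    @property
    def pixel_area_um2(self) -> float:
        """Area of one pixel in µm² (pixel_size_um squared)."""
        return self.pixel_size_um ** 2


def pixels_to_area_um2(n_pixels: int, cal: Calibration) -> float:
    """Convert a pixel count into a physical area in µm².

    The conversion is linear: ``n_pixels * cal.pixel_area_um2``.
    """
    if n_pixels < 0:
        raise ValueError(f"n_pixels must be >= 0, got {n_pixels}")
    return float(n_pixels) * cal.pixel_area_um2


@dataclass
class ZStack:
    """A calibrated multi-channel, multi-slice grayscale image volume.

    ``data`` is indexed ``(channel, slice, row, column)`` and holds
    non-negative integers of 8- or 16-bit depth. Library operations accept any
    channel count; the pipeline entry point requires exactly two channels
    (presynaptic and postsynaptic markers).
    """

    data: np.ndarray
    calibration: Calibration
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be 4-D (channel, slice, row, col), got shape {self.data.shape}"
            )
        if self.data.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
            raise ValueError(f"stack dtype must be uint8 or uint16, got {self.data.dtype}")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i + 1}" for i in range(self.n_channels))
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match the number of channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def bit_depth_max(self) -> int:
        """Largest representable intensity for the stack's dtype."""
        return int(np.iinfo(self.data.dtype).max)


@dataclass(frozen=True)
class RoiRegion:
    """A named simple polygon (one hemisomite) applied to every z-slice.

    Vertices are ``(row, column)`` points; the polygon is closed implicitly.
    A pixel is a member when its center is inside or on the boundary.
    """

    name: str
    vertices: tuple[tuple[float, float], ...]

    def __init__(self, name: str, vertices: Sequence[Sequence[float]]):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(
            self, "vertices", tuple((float(r), float(c)) for r, c in vertices)
        )
        if len(self.vertices) < 3:
            raise ValueError(f"ROI '{name}' needs >= 3 vertices, got {len(self.vertices)}")
        poly = self._polygon()
        if not poly.is_valid or poly.area == 0:
            raise ValueError(f"ROI '{name}' is degenerate or self-intersecting")

    def _polygon(self) -> shapely.Polygon:
        # shapely works in (x, y); map column -> x, row -> y.
        return shapely.Polygon([(c, r) for r, c in self.vertices])

    def bounds(self) -> tuple[float, float, float, float]:
        """(min_row, min_col, max_row, max_col) of the polygon."""
        rows = [r for r, _ in self.vertices]
        cols = [c for _, c in self.vertices]
        return min(rows), min(cols), max(rows), max(cols)


@dataclass
class BinaryMask:
    """A per-slice, per-channel boolean foreground map.

    ``provenance`` records (channel index, slice index, roi name) so that
    downstream tallies can attribute counts; it is optional for library use.
    """

    data: np.ndarray
    provenance: tuple[int, int, str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def rasterize_roi(roi: RoiRegion, shape: tuple[int, int]) -> BinaryMask:
    """Rasterize a polygonal ROI onto a pixel grid.

    A pixel (r, c) is foreground exactly when its center lies inside or on
    the boundary of the polygon. Raises if the polygon extends outside the
    frame.
    """
    rows, cols = shape
    min_r, min_c, max_r, max_c = roi.bounds()
    if min_r < 0 or min_c < 0 or max_r > rows - 1 or max_c > cols - 1:
        raise ValueError(
            f"ROI '{roi.name}' bounds {(min_r, min_c, max_r, max_c)} exceed frame {shape}"
        )
    poly = roi._polygon()
    lo_r, hi_r = int(np.floor(min_r)), int(np.ceil(max_r))
    lo_c, hi_c = int(np.floor(min_c)), int(np.ceil(max_c))
    rr, cc = np.meshgrid(
        np.arange(lo_r, hi_r + 1), np.arange(lo_c, hi_c + 1), indexing="ij"
    )
    # intersects == interior or boundary hit, i.e. "boundary counts as inside"
    inside = shapely.intersects_xy(poly, cc.ravel(), rr.ravel()).reshape(rr.shape)
    mask = np.zeros(shape, dtype=bool)
    mask[lo_r : hi_r + 1, lo_c : hi_c + 1] = inside
    return BinaryMask(mask)


# ---------------------------------------------------------------------------
# File I/O: TIFF stacks and ROI files
# ---------------------------------------------------------------------------

def read_rois(path: str | Path) -> list[RoiRegion]:
    """Read named polygonal ROIs from a JSON file.

    Schema: a JSON list of objects ``{"name": str, "vertices": [[row, col], ...]}``
    in pixel coordinates.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"ROI file {path} must contain a JSON list")
    return [RoiRegion(entry["name"], entry["vertices"]) for entry in raw]


def write_rois(rois: Sequence[RoiRegion], path: str | Path) -> None:
    payload = [
        {"name": roi.name, "vertices": [list(v) for v in roi.vertices]} for roi in rois
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    """Pixel size (µm) from TIFF resolution tags, if present and sane."""
    page = tif.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    if xres is None:
        return None
    num, den = xres.value
    if num == 0:
        return None
    pixels_per_unit = num / den
    unit_tag = tags.get("ResolutionUnit")
    unit = getattr(unit_tag, "value", None)
    # ImageJ-style TIFFs carry the unit in the ImageJ metadata instead.
    ij = tif.imagej_metadata or {}
    ij_unit = ij.get("unit", "")
    if ij_unit in ("um", "micron", "µm", "\\u00b5m"):
        return 1.0 / pixels_per_unit
    if unit is not None and getattr(unit, "name", str(unit)).upper().endswith("CENTIMETER"):
        return 1e4 / pixels_per_unit
    if ij_unit == "" and unit is not None:
        # Unit tag present but not interpretable as physical length.
        return None
    return None


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> ZStack:
    """Read a multi-page TIFF as a calibrated z-stack.

    Accepts 2-D (single slice, single channel), 3-D (slices × rows × cols) and
    4-D volumes; 4-D axes are taken from the TIFF series metadata (CZYX or
    ZCYX). Calibration priority: explicit ``pixel_size_um`` argument, then
    TIFF resolution tags, then the 0.21 µm/px default with a logged warning.
    """
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        tag_px = _pixel_size_from_tiff(tif)
        ij = tif.imagej_metadata or {}

    if data.ndim == 2:
        data = data[np.newaxis, np.newaxis]
    elif data.ndim == 3:
        data = data[np.newaxis]
    elif data.ndim == 4:
        if axes == "ZCYX":
            data = np.moveaxis(data, 1, 0)
        elif axes != "CZYX":
            raise ValueError(f"unsupported TIFF axes '{axes}' in {path}")
    else:
        raise ValueError(f"unsupported TIFF dimensionality {data.ndim} in {path}")

    if pixel_size_um is not None:
        px = pixel_size_um
    elif tag_px is not None:
        px = tag_px
    else:
        px = DEFAULT_PIXEL_SIZE_UM
        logger.warning(
            "%s: no pixel-size calibration found; falling back to %.2f um/px",
            path,
            px,
        )
    if z_step_um is None:
        z_step_um = float(ij.get("spacing", DEFAULT_Z_STEP_UM))
    cal = Calibration(pixel_size_um=px, z_step_um=z_step_um)
    names = tuple(channel_names) if channel_names else ()
    return ZStack(data=data, calibration=cal, channel_names=names)


def write_stack(stack: ZStack, path: str | Path) -> None:
    """Write a z-stack as an ImageJ-compatible calibrated TIFF (ZCYX pages)."""
    px = stack.calibration.pixel_size_um
    data = np.moveaxis(stack.data, 0, 1)  # (slice, channel, row, col)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tifffile.imwrite(
            str(path),
            data,
            imagej=True,
            resolution=(1.0 / px, 1.0 / px),
            metadata={
                "axes": "ZCYX",
                "unit": "um",
                "spacing": stack.calibration.z_step_um,
                "Labels": list(stack.channel_names),
            },
        )
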