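"""Image-series I/O, time-axis construction, plate layout and splitting.

A scanning run is a time-ordered stack of flatbed-scanner images, either a
full scan bed holding several Petri dishes or a single pre-cropped plate.
This module establishes the time axis from filenames, plans/locates the
circular plate regions, splits full-bed frames into per-plate frames (with
pixels outside the plate circle masked as NaN), and assembles visualisation
videos.

Conventions: the pixel grid is 0-based, x = column, y = row; centroids and
circle centres are sub-pixel floats; physical scale is
``pixel_size_mm = 25.4 / dpi``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Sequence

import imageio.v2 as iio
import numpy as np
from skimage import color, feature, transform, util

__all__ = [
    "ScanFrame",
    "PlateROI",
    "PlateSeries",
    "load_image",
    "parse_time_axis",
    "plan_layout",
    "rois_from_layout",
    "split_plates",
    "detect_plate_circle",
    "assemble_video",
]

#: Sentinel for pixels outside the plate circle. NaN is excluded from every
#: statistic downstream (background fits, thresholds, detections).
MASK_SENTINEL = float("nan")


@dataclass(frozen=True)
class ScanFrame:
    """One timed raster image in a series.

    ``image`` is a 2-D float array with intensities normalised to [0, 1];
    masked pixels (outside a plate circle) hold NaN.
    """

    index: int
    time_h: float
    image: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.image.ndim != 2 or min(self.image.shape) < 1:
            raise ValueError("ScanFrame.image must be a non-empty 2-D array")


@dataclass(frozen=True)
class PlateROI:
    """A circular plate region on a scan frame, in pixel coordinates."""

    plate_id: str
    center_x_px: float
    center_y_px: float
    radius_px: float
    pixel_size_mm: float

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError(f"radius_px must be > 0 (plate {self.plate_id})")
        if self.pixel_size_mm <= 0:
            raise ValueError(f"pixel_size_mm must be > 0 (plate {self.plate_id})")

    def contains(self, x: np.ndarray, y: np.ndarray, margin_px: float = 0.0) -> np.ndarray:
        """True where (x, y) lies inside the circle shrunk by ``margin_px``."""
        r = np.hypot(np.asarray(x) - self.center_x_px, np.asarray(y) - self.center_y_px)
        return r <= self.radius_px - margin_px


@dataclass
class PlateSeries:
    """One plate's ordered, cropped frames plus its (crop-local) ROI."""

    roi: PlateROI
    frames: list[ScanFrame] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {f.image.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("all frames of a PlateSeries must share dimensions")
        times = [f.time_h for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as a float intensity array in [0, 1].

    RGB(A) inputs are reduced to intensity by standard luminance weighting;
    8- and 16-bit integer images are scaled by their dtype range.
    """
    img = iio.imread(str(path))
    img = util.img_as_float(img)
    if img.ndim == 3:
        if img.shape[2] == 4:
            img = img[..., :3]
        img = color.rgb2gray(img)
    return np.clip(np.asarray(img, dtype=float), 0.0, 1.0)


_TS_FORMATS = ("%Y%m%d%H%M%S", "%Y-%m-%d_%H-%M-%S", "%Y%m%d_%H%M%S", "%H:%M:%S", "%H-%M-%S", "%H:%M", "%H%M")


def _parse_timestamp(text: str, ts_format: str | None) -> datetime | float:
    if ts_format is not None:
        return datetime.strptime(text, ts_format)
    try:
        return float(text)  # plain number: minutes are ambiguous, treat as hours
    except ValueError:
        pass
    for fmt in _TS_FORMATS:
        try:
            return datetime.strptime(text, fmt)
        except ValueError:
            continue
    raise ValueError(f"cannot interpret timestamp {text!r}; pass ts_format")


def parse_time_axis(
    filenames: Sequence[str],
    mode: str = "interval",
    interval_min: float | None = None,
    pattern: str | None = None,
    ts_format: str | None = None,
) -> list[tuple[str, float]]:
    """Build the acquisition time axis from a list of filenames.

    In ``interval`` mode frames are assumed equally spaced by ``interval_min``
    minutes (the scanner cadence, e.g. every 5, 15 or 30 min); filenames are
    sorted lexicographically and times assigned in order. In ``pattern`` mode
    ``pattern`` is a regex whose first group (or group named ``ts``) extracts
    a timestamp from every filename; frames are sorted by timestamp.

    Returns one ``(filename, time_h)`` pair per input, sorted by time, with
    the first frame at 0.0 h.
    """
    if not filenames:
        raise ValueError("filenames must be non-empty")
    if mode == "interval":
        if interval_min is None or interval_min <= 0:
            raise ValueError("interval mode requires interval_min > 0")
        ordered = sorted(filenames)
        return [(name, i * interval_min / 60.0) for i, name in enumerate(ordered)]
    if mode != "pattern":
        raise ValueError(f"unknown mode {mode!r}")
    if pattern is None:
        raise ValueError("pattern mode requires a pattern")
    rx = re.compile(pattern)
    stamps: list[tuple[datetime | float, str]] = []
    for name in filenames:
        m = rx.search(name)
        if m is None:
            raise ValueError(f"pattern does not match filename {name!r}")
        raw = m.groupdict().get("ts") or m.group(1)
        stamps.append((_parse_timestamp(raw, ts_format), name))
    seen: dict[object, str] = {}
    for ts, name in stamps:
        if ts in seen:
            raise ValueError(f"duplicate timestamp {ts} in files {seen[ts]!r} and {name!r}")
        seen[ts] = name
    stamps.sort(key=lambda p: p[0])
    t0 = stamps[0][0]
    out = []
    for ts, name in stamps:
        if isinstance(ts, datetime):
            dt_h = (ts - t0).total_seconds() / 3600.0
        else:
            dt_h = float(ts) - float(t0)
        out.append((name, dt_h))
    return out


def plan_layout(
    scan_w_mm: float,
    scan_h_mm: float,
    plate_diameter_mm: float,
    margin_mm: float = 0.0,
) -> list[tuple[float, float]]:
    """Plan an axis-aligned grid of plate centres on the scan bed (mm).

    Packs ``floor(w/(d+m)) x floor(h/(d+m))`` non-overlapping circles and
    centres the whole grid on the bed. The standard A4-class bed
    (216 mm x 297 mm) holds a 2 x 3 grid of six 3-inch (76.2 mm) dishes.
    A plate larger than the bed yields an empty list.
    """
    if scan_w_mm <= 0 or scan_h_mm <= 0 or plate_diameter_mm <= 0 or margin_mm < 0:
        raise ValueError("bed and plate dimensions must be positive, margin non-negative")
    pitch = plate_diameter_mm + margin_mm
    cols = int(scan_w_mm // pitch)
    rows = int(scan_h_mm // pitch)
    if cols == 0 or rows == 0:
        return []
    x0 = (scan_w_mm - cols * pitch) / 2.0 + pitch / 2.0
    y0 = (scan_h_mm - rows * pitch) / 2.0 + pitch / 2.0
    return [(x0 + c * pitch, y0 + r * pitch) for r in range(rows) for c in range(cols)]


def rois_from_layout(
    centers_mm: Sequence[tuple[float, float]],
    plate_diameter_mm: float,
    dpi: float,
    plate_ids: Sequence[str] | None = None,
    snap_to_pixel: bool = True,
) -> list[PlateROI]:
    """Convert planned mm centres into pixel-space :class:`PlateROI` objects.

    ``snap_to_pixel`` rounds centres and radii to integers so that bounding
    squares align with the pixel grid (lossless crop/compose round trips).
    """
    if dpi <= 0:
        raise ValueError("dpi must be > 0")
    px_mm = 25.4 / dpi
    rois = []
    for i, (cx_mm, cy_mm) in enumerate(centers_mm):
        pid = plate_ids[i] if plate_ids is not None else f"plate{i + 1}"
        cx, cy = cx_mm / px_mm, cy_mm / px_mm
        r = plate_diameter_mm / 2.0 / px_mm
        if snap_to_pixel:
            cx, cy, r = round(cx), round(cy), round(r)
        rois.append(PlateROI(pid, float(cx), float(cy), float(r), px_mm))
    return rois


def _crop_bounds(roi: PlateROI) -> tuple[int, int, int]:
    side = int(math.ceil(2 * roi.radius_px))
    x0 = int(round(roi.center_x_px - side / 2.0))
    y0 = int(round(roi.center_y_px - side / 2.0))
    return x0, y0, side


def split_plates(frame: ScanFrame, rois: Sequence[PlateROI]) -> list[ScanFrame]:
    """Crop one full-bed frame into per-plate frames.

    Each crop is the ROI's axis-aligned bounding square (side = 2*radius,
    rounded up); pixels outside the circle are set to NaN. An ROI whose
    circle extends beyond the frame raises, naming the plate.
    """
    h, w = frame.image.shape
    out = []
    for roi in rois:
        x0, y0, side = _crop_bounds(roi)
        if x0 < 0 or y0 < 0 or x0 + side > w or y0 + side > h:
            raise ValueError(f"plate {roi.plate_id!r}: ROI extends beyond the frame")
        crop = frame.image[y0 : y0 + side, x0 : x0 + side].astype(float, copy=True)
        yy, xx = np.mgrid[0:side, 0:side]
        local_cx, local_cy = roi.center_x_px - x0, roi.center_y_px - y0
        outside = np.hypot(xx - local_cx, yy - local_cy) > roi.radius_px
        crop[outside] = MASK_SENTINEL
        out.append(ScanFrame(frame.index, frame.time_h, crop, frame.source_path))
    return out


def local_roi(roi: PlateROI) -> PlateROI:
    """The same plate ROI expressed in its own crop's coordinates."""
    x0, y0, _ = _crop_bounds(roi)
    return replace(roi, center_x_px=roi.center_x_px - x0, center_y_px=roi.center_y_px - y0)


def split_series(
    frames: Sequence[ScanFrame], rois: Sequence[PlateROI]
) -> list[PlateSeries]:
    """Split a full-bed frame series into one :class:`PlateSeries` per ROI."""
    per_plate: list[list[ScanFrame]] = [[] for _ in rois]
    for frame in frames:
        for i, crop in enumerate(split_plates(frame, rois)):
            per_plate[i].append(crop)
    return [PlateSeries(local_roi(roi), crops) for roi, crops in zip(rois, per_plate)]


def detect_plate_circle(
    image: np.ndarray,
    expected_radius_px: float,
    tolerance_frac: float = 0.1,
    pixel_size_mm: float = 1.0,
    plate_id: str = "plate",
    hint_center: tuple[float, float] | None = None,
    hint_window_px: float | None = None,
    accum_threshold: float = 0.25,
) -> PlateROI | None:
    """Locate a plate rim by a circular Hough transform.

    Searches radii within ``expected_radius_px * (1 +/- tolerance_frac)``.
    With ``hint_center``, the accumulator is restricted to a window around
    the hint so a specific plate can be picked out of several. Returns None
    when no circle reaches ``accum_threshold`` (caller falls back to the
    configured ROI).
    """
    if expected_radius_px <= 0:
        raise ValueError("expected_radius_px must be > 0")
    if not 0 < tolerance_frac < 1:
        raise ValueError("tolerance_frac must be in (0, 1)")
    img = np.nan_to_num(image, nan=float(np.nanmedian(image)) if np.isfinite(image).any() else 0.0)
    lo = max(3, int(math.floor(expected_radius_px * (1 - tolerance_frac))))
    hi = int(math.ceil(expected_radius_px * (1 + tolerance_frac)))
    radii = np.arange(lo, hi + 1)
    edges = feature.canny(img, sigma=2.0)
    if not edges.any():
        return None
    accum = transform.hough_circle(edges, radii)
    if hint_center is not None:
        win = hint_window_px if hint_window_px is not None else expected_radius_px / 2.0
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        inside = np.hypot(xx - hint_center[0], yy - hint_center[1]) <= win
        accum = accum * inside[None, :, :]
    peak = float(accum.max())
    if peak < accum_threshold:
        return None
    ir, iy, ix = np.unravel_index(int(accum.argmax()), accum.shape)
    return PlateROI(plate_id, float(ix), float(iy), float(radii[ir]), pixel_size_mm)


def assemble_video(
    frames: Sequence[ScanFrame], out_path: str | Path, fps: float = 10.0
) -> Path:
    """Write the frame series as an animation for visual inspection.

    Containers: animated GIF (``.gif``) or multi-page TIFF (``.tif/.tiff``),
    both dependency-light and frame-exact. Frames are written in input order,
    one video frame per scan frame, masked pixels rendered black.
    """
    if not frames:
        raise ValueError("frames must be non-empty")
    if fps <= 0:
        raise ValueError("fps must be > 0")
    shapes = {f.image.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError("all frames must share dimensions")
    stack = np.stack(
        [np.nan_to_num(np.clip(f.image, 0, 1), nan=0.0) for f in frames]
    )
    stack_u8 = (stack * 255).round().astype(np.uint8)
    out_path = Path(out_path)
    suffix = out_path.suffix.lower()
    if suffix == ".gif":
        iio.mimwrite(out_path, list(stack_u8), format="GIF", duration=1.0 / fps, loop=0)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(out_path, stack_u8, photometric="minisblack")
    else:
        raise ValueError(f"unsupported video container {suffix!r} (use .gif or .tif)")
    return out_path
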