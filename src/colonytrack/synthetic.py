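"""Synthetic scanner-style plate time-lapse generator with ground truth.

Emulates the study conditions of a flatbed-scanner colony-tracking run:
circular agar plates on a scan bed, colonies appearing at per-colony lag
times drawn from 5-8 h, areas following a logistic rise to saturation,
smooth background shading (base + linear ramp + radial vignette), and
additive Gaussian pixel noise. Every run returns the exact per-colony
parameters and per-frame rasterised areas, so each pipeline stage can be
scored against truth without any real scans.

The default :class:`SceneSpec` mirrors a typical run: an A4-class
216 x 297 mm bed, six 3-inch (76.2 mm) plates, ~50 colonies per plate
(a mid-range plating density), scans every 15 min for 20 h, lag times
uniform on 5-8 h. The synthetic resolution defaults to 100 dpi — far below
real scanner resolutions but preserving the geometry and statistics at
tractable image sizes.

Each colony's half-saturation time is placed so that its analytic area
equals the detection-limit area exactly at its lag time:
``t50 = lag + ln(K / A_det - 1) / mu``; before the lag the colony is not
rendered and its true area is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

from .kinetics import logistic_area
from .plate_io import PlateROI, ScanFrame, plan_layout, rois_from_layout

__all__ = ["SceneSpec", "ColonyTruth", "GroundTruth", "simulate_series", "ground_truth_table", "single_plate_spec"]


@dataclass(frozen=True)
class SceneSpec:
    """Full parameterisation of one synthetic scanning run."""

    seed: int = 0
    bed_mm: tuple[float, float] = (216.0, 297.0)
    dpi: float = 100.0
    plate_diameter_mm: float = 76.2
    plate_layout: tuple[PlateROI, ...] | None = None  # None -> planned grid
    colonies_per_plate: int = 50
    lag_h: tuple[float, float] = (5.0, 8.0)  # uniform support, hours
    K_mm2: tuple[float, float] = (3.0, 12.0)  # saturation area, uniform, mm^2
    mu_per_h: tuple[float, float] = (0.8, 1.5)  # logistic rate, uniform
    colony_contrast: float = 0.35
    background_base: float = 0.45
    background_ramp: tuple[float, float] = (0.03, 0.02)  # across bed, x/y
    vignette_strength: float = 0.05
    bed_intensity: float = 0.12  # bed outside the plates
    noise_sigma: float = 0.02
    interval_min: float = 15.0
    duration_h: float = 20.0
    min_center_spacing_px: float = 25.0
    placement_margin_frac: float = 0.15  # keep-out band at the rim
    detection_limit_area_px2: float = 2.0
    touching_scenario: bool = False  # deliberately place merging pairs
    edge_soft_px: float = 0.5  # Gaussian edge sigma of the rendered disk

    def __post_init__(self) -> None:
        if self.duration_h <= 0 or self.interval_min <= 0:
            raise ValueError("duration_h and interval_min must be > 0")
        if self.colonies_per_plate < 0:
            raise ValueError("colonies_per_plate must be >= 0")
        for name in ("lag_h", "K_mm2", "mu_per_h"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0 and name != "lag_h":
                raise ValueError(f"{name} support must be positive and ordered")

    @property
    def pixel_size_mm(self) -> float:
        return 25.4 / self.dpi

    def times_h(self) -> np.ndarray:
        n = int(math.floor(self.duration_h * 60.0 / self.interval_min)) + 1
        return np.arange(n) * self.interval_min / 60.0

    def rois(self) -> list[PlateROI]:
        if self.plate_layout is not None:
            return list(self.plate_layout)
        centers = plan_layout(*self.bed_mm, self.plate_diameter_mm)
        return rois_from_layout(centers, self.plate_diameter_mm, self.dpi)


@dataclass(frozen=True)
class ColonyTruth:
    plate_id: str
    colony_id: int
    center_x_px: float  # bed coordinates
    center_y_px: float
    lag_h: float
    K_px2: float
    mu: float
    t50_h: float


@dataclass
class GroundTruth:
    """Per-colony parameters plus per-frame rasterised areas."""

    spec: SceneSpec
    colonies: list[ColonyTruth]
    # one record per (colony, frame): true rasterised area + touching flag
    frame_records: list[dict] = field(default_factory=list)

    def colony(self, plate_id: str, colony_id: int) -> ColonyTruth:
        for c in self.colonies:
            if c.plate_id == plate_id and c.colony_id == colony_id:
                return c
        raise KeyError((plate_id, colony_id))


def _place_colonies(
    rng: np.random.Generator,
    roi: PlateROI,
    n: int,
    min_spacing_px: float,
    margin_px: float,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample n centres in the plate disk at pairwise min spacing."""
    r_max = roi.radius_px - margin_px
    if r_max <= 0 and n > 0:
        raise ValueError("placement margin leaves no room on the plate")
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n} colonies at spacing {min_spacing_px} px "
                f"on plate {roi.plate_id!r} after {max_tries} tries"
            )
        tries += 1
        rad = r_max * np.sqrt(rng.uniform())
        ang = rng.uniform(0, 2 * np.pi)
        x = roi.center_x_px + rad * np.cos(ang)
        y = roi.center_y_px + rad * np.sin(ang)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_spacing_px**2 for px, py in pts):
            pts.append((x, y))
    return np.array(pts).reshape(n, 2)


def _render_disk(image: np.ndarray, cx: float, cy: float, radius: float, amplitude: float, edge_sigma: float) -> np.ndarray | None:
    """Add a soft-edged disk to ``image``; returns its binary (>=50%) mask
    restricted to the touched window, as (ys, xs, mask) via a boolean array
    the size of the window plus offsets packed in attributes."""
    h, w = image.shape
    pad = radius + 4 * edge_sigma + 1
    x0, x1 = int(max(0, math.floor(cx - pad))), int(min(w, math.ceil(cx + pad) + 1))
    y0, y1 = int(max(0, math.floor(cy - pad))), int(min(h, math.ceil(cy + pad) + 1))
    if x0 >= x1 or y0 >= y1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx, yy - cy)
    cov = 0.5 * erfc((d - radius) / (math.sqrt(2.0) * edge_sigma))
    image[y0:y1, x0:x1] += amplitude * cov
    full = np.zeros(image.shape, dtype=bool)
    full[y0:y1, x0:x1] = cov >= 0.5
    return full


def _background_bed(spec: SceneSpec, rois: Sequence[PlateROI], shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    bg = np.full(shape, spec.bed_intensity, dtype=float)
    ramp = (
        spec.background_ramp[0] * (xx / max(w - 1, 1))
        + spec.background_ramp[1] * (yy / max(h - 1, 1))
    )
    for roi in rois:
        d = np.hypot(xx - roi.center_x_px, yy - roi.center_y_px)
        inside = d <= roi.radius_px
        vign = spec.vignette_strength * (d / roi.radius_px) ** 2
        bg[inside] = (spec.background_base + ramp - vign)[inside]
    return bg


def simulate_series(spec: SceneSpec) -> tuple[list[ScanFrame], GroundTruth]:
    """Render the full-bed frame series and its ground truth.

    Deterministic: identical spec (including seed) gives bit-identical
    frames and truth. Colony areas follow the logistic law; a colony is
    rendered from its lag time on as a soft-edged disk of radius
    ``sqrt(A/pi)`` added to the plate background, and the truth records its
    rasterised (>= half-coverage) pixel area per frame plus whether its mask
    touches another colony's.
    """
    rng = np.random.default_rng(spec.seed)
    rois = spec.rois()
    px = spec.pixel_size_mm
    w = int(math.ceil(spec.bed_mm[0] / px))
    h = int(math.ceil(spec.bed_mm[1] / px))
    times = spec.times_h()

    colonies: list[ColonyTruth] = []
    max_r_px = math.sqrt((spec.K_mm2[1] / px**2) / math.pi)
    margin = spec.placement_margin_frac * min(r.radius_px for r in rois) + max_r_px if rois else 0.0
    for roi in rois:
        n = spec.colonies_per_plate
        centers = _place_colonies(rng, roi, n, spec.min_center_spacing_px, margin)
        if spec.touching_scenario and n >= 2:
            # move colony 1 next to colony 0 so their final disks fuse
            centers[1] = centers[0] + np.array([0.6 * max_r_px, 0.0])
        lags = rng.uniform(*spec.lag_h, size=n)
        Ks = rng.uniform(*spec.K_mm2, size=n) / px**2
        mus = rng.uniform(*spec.mu_per_h, size=n)
        for i in range(n):
            a_det = min(spec.detection_limit_area_px2, 0.5 * Ks[i])
            t50 = lags[i] + math.log(Ks[i] / a_det - 1.0) / mus[i]
            colonies.append(
                ColonyTruth(
                    plate_id=roi.plate_id,
                    colony_id=i,
                    center_x_px=float(centers[i, 0]),
                    center_y_px=float(centers[i, 1]),
                    lag_h=float(lags[i]),
                    K_px2=float(Ks[i]),
                    mu=float(mus[i]),
                    t50_h=float(t50),
                )
            )

    bg = _background_bed(spec, rois, (h, w))
    frames: list[ScanFrame] = []
    records: list[dict] = []
    for k, t in enumerate(times):
        img = bg.copy()
        masks: list[tuple[ColonyTruth, np.ndarray | None]] = []
        for col in colonies:
            if t < col.lag_h:
                masks.append((col, None))
                continue
            area = float(logistic_area(t, col.K_px2, col.mu, col.t50_h))
            radius = math.sqrt(area / math.pi)
            m = _render_disk(
                img, col.center_x_px, col.center_y_px, radius, spec.colony_contrast, spec.edge_soft_px
            )
            masks.append((col, m))
        # touching: label the union of binary masks, colonies sharing a
        # component are in contact
        union = np.zeros((h, w), dtype=bool)
        for _, m in masks:
            if m is not None:
                union |= m
        touching_ids: set[int] = set()
        if union.any():
            from skimage import measure

            lab = measure.label(union, connectivity=2)
            owners: dict[int, list[int]] = {}
            for idx, (_, m) in enumerate(masks):
                if m is None:
                    continue
                labs = np.unique(lab[m])
                labs = labs[labs > 0]
                for lv in labs:
                    owners.setdefault(int(lv), []).append(idx)
            for ids in owners.values():
                if len(ids) > 1:
                    touching_ids.update(ids)
        for idx, (col, m) in enumerate(masks):
            records.append(
                dict(
                    plate_id=col.plate_id,
                    colony_id=col.colony_id,
                    frame=k,
                    time_h=float(t),
                    true_area_px2=float(m.sum()) if m is not None else 0.0,
                    touching_any=idx in touching_ids,
                )
            )
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        frames.append(
            ScanFrame(index=k, time_h=float(t), image=np.clip(img, 0.0, 1.0).astype(np.float32), source_path=f"synthetic:{k}")
        )
    return frames, GroundTruth(spec=spec, colonies=colonies, frame_records=records)


def ground_truth_table(gt: GroundTruth) -> pd.DataFrame:
    """Long-format truth table, one row per (colony, frame).

    Columns: plate_id, colony_id, frame, time_h, true_area_px2, lag_h, K,
    mu; sorted by (plate_id, colony_id, frame).
    """
    params = {
        (c.plate_id, c.colony_id): c for c in gt.colonies
    }
    rows = []
    for rec in gt.frame_records:
        c = params[(rec["plate_id"], rec["colony_id"])]
        rows.append(
            dict(
                plate_id=rec["plate_id"],
                colony_id=rec["colony_id"],
                frame=rec["frame"],
                time_h=rec["time_h"],
                true_area_px2=rec["true_area_px2"],
                lag_h=c.lag_h,
                K=c.K_px2,
                mu=c.mu,
            )
        )
    cols = ["plate_id", "colony_id", "frame", "time_h", "true_area_px2", "lag_h", "K", "mu"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["plate_id", "colony_id", "frame"], kind="stable").reset_index(drop=True)


def single_plate_spec(**overrides) -> SceneSpec:
    """A spec whose bed holds exactly one centred plate (handy for tests
    and per-plate benchmarks); keyword overrides apply on top."""
    diameter = overrides.pop("plate_diameter_mm", 76.2)
    dpi = overrides.pop("dpi", 100.0)
    px = 25.4 / dpi
    pad_mm = 4.0 * px
    bed = (diameter + 2 * pad_mm, diameter + 2 * pad_mm)
    r_px = round(diameter / 2.0 / px)
    c_px = round(bed[0] / 2.0 / px)
    roi = PlateROI("plate1", float(c_px), float(c_px), float(r_px), px)
    defaults = dict(
        bed_mm=bed,
        dpi=dpi,
        plate_diameter_mm=diameter,
        plate_layout=(roi,),
        colonies_per_plate=30,
    )
    defaults.update(overrides)
    return SceneSpec(**defaults)
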