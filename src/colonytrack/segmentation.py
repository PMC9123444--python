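"""Background estimation/subtraction and per-frame colony segmentation.

Colonies on a flatbed scan sit on a smoothly shaded agar background. The
pipeline first models that background (a user-picked reference region or a
fitted smooth surface), subtracts it so colony pixels become positive
residuals, thresholds the residual, and extracts labelled connected
components with shape features. Components that look fused (low circularity
or multiple intensity maxima) or that sit near the plate rim are flagged —
never deleted — so downstream stages can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .plate_io import PlateROI

__all__ = [
    "Detection",
    "BackgroundModel",
    "estimate_background",
    "subtract_background",
    "segment_frame",
    "flag_exclusions",
]


@dataclass(frozen=True)
class Detection:
    """One segmented colony candidate in one frame."""

    frame_index: int
    label: int
    centroid_x_px: float
    centroid_y_px: float
    area_px2: float
    equivalent_diameter_px: float
    perimeter_px: float
    circularity: float
    touches_edge: bool = False
    touching_flag: bool = False


@dataclass(frozen=True)
class BackgroundModel:
    """Scalar (``region_mean``) or per-pixel (``surface``) background."""

    mode: str
    value_or_field: float | np.ndarray


def _finite(values: np.ndarray) -> np.ndarray:
    return values[np.isfinite(values)]


def estimate_background(
    frame_image: np.ndarray,
    mode: str = "surface",
    region: tuple[int, int, int, int] | None = None,
    poly_order: int = 2,
    n_robust_iter: int = 3,
) -> BackgroundModel:
    """Model the agar/scanner background of one plate frame.

    ``region_mean`` reproduces the cursor-picked reference patch: ``region``
    is ``(x0, y0, width, height)`` in pixels and must contain at least 25
    unmasked pixels; the model is its mean intensity. ``surface`` fits a
    low-order 2-D polynomial to all in-mask pixels with iterative rejection
    of bright outliers, capturing shading gradients without tracking
    colonies.
    """
    img = np.asarray(frame_image, dtype=float)
    if mode == "region_mean":
        if region is None:
            raise ValueError("region_mean mode requires a region")
        x0, y0, w, h = region
        if x0 < 0 or y0 < 0 or x0 + w > img.shape[1] or y0 + h > img.shape[0]:
            raise ValueError("background region lies outside the frame")
        patch = _finite(img[y0 : y0 + h, x0 : x0 + w])
        if patch.size < 25:
            raise ValueError(
                f"background region has only {patch.size} unmasked pixels (need >= 25)"
            )
        return BackgroundModel("region_mean", float(patch.mean()))
    if mode != "surface":
        raise ValueError(f"unknown background mode {mode!r}")

    mask = np.isfinite(img)
    if mask.sum() < (poly_order + 1) * (poly_order + 2) // 2:
        raise ValueError("too few unmasked pixels for a surface fit")
    yy, xx = np.nonzero(mask)
    # normalized coords keep the Vandermonde well conditioned
    xs = xx / max(img.shape[1] - 1, 1)
    ys = yy / max(img.shape[0] - 1, 1)
    cols = [
        xs**i * ys**j
        for i in range(poly_order + 1)
        for j in range(poly_order + 1 - i)
    ]
    design = np.stack(cols, axis=1)
    vals = img[yy, xx]
    keep = np.ones(vals.shape, dtype=bool)
    coef = np.zeros(design.shape[1])
    for _ in range(max(1, n_robust_iter)):
        coef, *_ = np.linalg.lstsq(design[keep], vals[keep], rcond=None)
        resid = vals - design @ coef
        sigma = 1.4826 * np.median(np.abs(resid[keep] - np.median(resid[keep])))
        if sigma <= 0:
            break
        # colonies are outliers on one side; reject asymmetrically on both
        keep = np.abs(resid) < 2.5 * sigma
        if keep.sum() < design.shape[1]:
            keep = np.ones(vals.shape, dtype=bool)
            break
    field = np.full(img.shape, np.nan)
    field[yy, xx] = design @ coef
    return BackgroundModel("surface", field)


def subtract_background(
    frame_image: np.ndarray,
    model: BackgroundModel,
    polarity: str = "bright",
) -> np.ndarray:
    """Subtract the background so colony pixels become positive residuals.

    ``bright`` assumes colonies brighter than agar (typical on a flatbed
    scan), ``dark`` the opposite; ``auto`` picks the sign whose rectified
    residual carries more total mass. Masked pixels stay NaN.
    """
    img = np.asarray(frame_image, dtype=float)
    bg = model.value_or_field
    if isinstance(bg, np.ndarray) and bg.shape != img.shape:
        raise ValueError("background field shape does not match the image")
    diff = img - bg
    bright = np.maximum(diff, 0.0)
    dark = np.maximum(-diff, 0.0)
    if polarity == "bright":
        res = bright
    elif polarity == "dark":
        res = dark
    elif polarity == "auto":
        res = bright if np.nansum(bright) >= np.nansum(dark) else dark
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    res = res.copy()
    res[~np.isfinite(img)] = np.nan
    return res


def _noise_sigma(values: np.ndarray) -> float:
    """Robust noise sigma of a zero-clipped residual.

    Background pixels dominate and follow max(N(0, sigma), 0), whose 84.1st
    percentile equals sigma; that quantile stays robust when colonies add a
    small bright tail. Falls back to the MAD for unclipped inputs.
    """
    q = float(np.quantile(values, 0.841))
    if q > 0:
        return q
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


def segment_frame(
    residual: np.ndarray,
    frame_index: int = 0,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    min_area_px2: int = 5,
    connectivity: int = 8,
) -> tuple[np.ndarray, list[Detection]]:
    """Threshold a background-subtracted frame and extract colony candidates.

    Otsu's threshold is computed on in-mask residual values with a floor of
    3x the noise sigma (median absolute deviation), so an empty plate yields
    no spurious foreground. Connected components (4- or 8-adjacency) smaller
    than ``min_area_px2`` are dropped; survivors are relabelled 1..n in
    raster order of their first pixel, and one :class:`Detection` with shape
    features is produced per label.

    Returns ``(labeled_mask, detections)``; the mask is int32, 0 = background.
    """
    if min_area_px2 < 1:
        raise ValueError("min_area_px2 must be >= 1")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    res = np.asarray(residual, dtype=float)
    finite = np.isfinite(res)
    vals = res[finite]
    labeled = np.zeros(res.shape, dtype=np.int32)
    if vals.size == 0:
        return labeled, []
    if threshold_method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed threshold method requires fixed_threshold")
        thr = float(fixed_threshold)
    elif threshold_method == "otsu":
        if np.ptp(vals) == 0:
            return labeled, []  # undefined threshold -> no foreground
        thr = float(filters.threshold_otsu(vals))
        thr = max(thr, 3.0 * _noise_sigma(vals))
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")

    fg = finite & (res >= thr) & (res > 0)
    raw = measure.label(fg, connectivity=2 if connectivity == 8 else 1)
    if raw.max() == 0:
        return labeled, []
    sizes = np.bincount(raw.ravel())
    keep_ids = np.nonzero(sizes >= min_area_px2)[0]
    keep_ids = keep_ids[keep_ids > 0]
    # relabel surviving components 1..n by raster order of first pixel
    flat = raw.ravel()
    uniq, first_idx = np.unique(flat, return_index=True)
    first_pix = {int(l): int(i) for l, i in zip(uniq, first_idx) if l > 0}
    ranked = sorted((int(l) for l in keep_ids), key=lambda l: first_pix[l])
    remap = np.zeros(sizes.size, dtype=np.int32)
    for new, old in enumerate(ranked, start=1):
        remap[old] = new
    labeled = remap[raw]

    detections: list[Detection] = []
    for prop in measure.regionprops(labeled):
        area = float(prop.area)
        perim = float(prop.perimeter)
        circ = 1.0 if perim <= 0 else min(1.0, 4.0 * np.pi * area / perim**2)
        cy, cx = prop.centroid
        detections.append(
            Detection(
                frame_index=frame_index,
                label=int(prop.label),
                centroid_x_px=float(cx),
                centroid_y_px=float(cy),
                area_px2=area,
                equivalent_diameter_px=2.0 * np.sqrt(area / np.pi),
                perimeter_px=perim,
                circularity=circ,
            )
        )
    return labeled, detections


def flag_exclusions(
    detections: Sequence[Detection],
    labeled_mask: np.ndarray,
    residual: np.ndarray,
    plate_roi: PlateROI,
    circularity_min: float = 0.6,
    edge_margin_px: float | None = None,
    smooth_sigma: float = 1.0,
    peak_min_distance: int = 3,
) -> list[Detection]:
    """Flag fused and rim-adjacent colony candidates for exclusion.

    ``touching_flag`` is raised when circularity falls below
    ``circularity_min`` (fused blobs are non-circular) or the component
    carries more than one regional intensity maximum after Gaussian
    smoothing. ``touches_edge`` is raised when any component pixel lies
    within ``edge_margin_px`` (default 2% of plate radius) of the plate rim.
    Flags annotate; nothing is deleted here.
    """
    if edge_margin_px is None:
        edge_margin_px = 0.02 * plate_roi.radius_px
    smooth = ndimage.gaussian_filter(np.nan_to_num(residual, nan=0.0), smooth_sigma)
    # regional maxima per component, prominence-gated (h-maxima) so pixel
    # noise on a colony's flat top never splits it into false "peaks"
    n_peaks = np.zeros(int(labeled_mask.max()) + 1, dtype=int)
    slices = ndimage.find_objects(labeled_mask)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        comp = labeled_mask[sl] == lab
        sub = np.where(comp, smooth[sl], 0.0)
        peak = float(sub.max())
        if peak <= 0:
            n_peaks[lab] = 1
            continue
        hm = morphology.h_maxima(sub, 0.3 * peak)
        n_peaks[lab] = int(measure.label(hm & comp, connectivity=2).max())

    # labels owning any pixel in the rim band, found in one pass
    yy, xx = np.mgrid[0 : labeled_mask.shape[0], 0 : labeled_mask.shape[1]]
    rim_band = ~plate_roi.contains(xx, yy, margin_px=edge_margin_px)
    rim_labels = set(np.unique(labeled_mask[rim_band & (labeled_mask > 0)]).tolist())

    out: list[Detection] = []
    for det in detections:
        touching = det.circularity < circularity_min or n_peaks[det.label] > 1
        out.append(
            replace(det, touching_flag=bool(touching), touches_edge=det.label in rim_labels)
        )
    return out
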