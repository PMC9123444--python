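"""Emergence (lag) times, logistic growth fits, and per-plate CFU summaries.

A colony's projected area rises exponentially once it becomes detectable
and saturates as growth slows, which the logistic law

    A(t) = K / (1 + exp(-mu * (t - t50)))

captures with three parameters: carrying capacity ``K`` (area units),
per-hour rate ``mu``, and half-saturation time ``t50``. The lag (emergence)
time is operationalised as the first sustained detection: the earliest
recorded point from which the area stays at or above a detection-limit
area for a set number of consecutive points. Plate-level CFU counts apply
the standard plate-count validity convention: only plates bearing 25-250
colonies are statistically reliable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .tracking import ColonyTrack

__all__ = [
    "GrowthFit",
    "PlateSummary",
    "InsufficientDataError",
    "logistic_area",
    "emergence_time",
    "assign_emergence",
    "fit_growth",
    "fit_track",
    "summarize_plate",
    "classify_cfu_count",
    "default_area_min_px2",
]

#: inclusive CFU validity bounds (plate-count convention)
CFU_VALID_RANGE = (25, 250)

#: optimiser box constraints; a fit pressed against them is not converged
MU_MAX_PER_H = 50.0
K_MAX_FACTOR = 10.0


class InsufficientDataError(ValueError):
    """Raised when a growth fit has too few usable points (distinct from
    optimizer non-convergence, which returns ``converged=False``)."""


@dataclass(frozen=True)
class GrowthFit:
    track_id: int
    K: float
    mu: float
    t50_h: float
    rss: float
    r2: float
    converged: bool


@dataclass(frozen=True)
class PlateSummary:
    plate_id: str
    cfu_count: int
    valid: bool
    invalid_reason: str  # below_range | above_range | none
    n_merged_excluded: int
    n_edge_excluded: int


def logistic_area(t, K, mu, t50):
    """Logistic (saturating-exponential) colony-area law."""
    return K / (1.0 + np.exp(-mu * (np.asarray(t, dtype=float) - t50)))


def _logistic_jac(t, K, mu, t50):
    t = np.asarray(t, dtype=float)
    e = np.exp(-mu * (t - t50))
    denom = (1.0 + e) ** 2
    dK = 1.0 / (1.0 + e)
    dmu = K * (t - t50) * e / denom
    dt50 = -K * mu * e / denom
    return np.stack([dK, dmu, dt50], axis=1)


def default_area_min_px2(dpi: float, min_area_px2: int = 5) -> float:
    """Detection-limit area: a 0.3 mm diameter disk at this dpi, but never
    below the segmentation minimum component size."""
    px_mm = 25.4 / dpi
    disk = np.pi * (0.15 / px_mm) ** 2
    return float(max(min_area_px2, disk))


def emergence_time(
    track: ColonyTrack, area_min_px2: float, persist_frames: int = 2
) -> float | None:
    """Time of first sustained detection, or None if never sustained.

    Returns the ``time_h`` of the first recorded point from which the area
    stays >= ``area_min_px2`` for ``persist_frames`` consecutive recorded
    points (a colony only enters the record once it is segmentable, so the
    track's first point is eligible).
    """
    if persist_frames < 1:
        raise ValueError("persist_frames must be >= 1")
    pts = track.points
    n = len(pts)
    for i in range(n - persist_frames + 1):
        if all(pts[i + j].area_px2 >= area_min_px2 for j in range(persist_frames)):
            return pts[i].time_h
    return None


def assign_emergence(
    tracks: Sequence[ColonyTrack], area_min_px2: float, persist_frames: int = 2
) -> None:
    """Set ``emergence_time_h`` on every track in place."""
    for trk in tracks:
        trk.emergence_time_h = emergence_time(trk, area_min_px2, persist_frames)


def _initial_guess(t: np.ndarray, a: np.ndarray) -> tuple[float, float, float]:
    K0 = float(a.max())
    half = K0 / 2.0
    above = np.nonzero(a >= half)[0]
    if above.size and above[0] > 0:
        i = above[0]
        # linear interpolation of the half-max crossing
        f = (half - a[i - 1]) / max(a[i] - a[i - 1], 1e-12)
        t50_0 = float(t[i - 1] + f * (t[i] - t[i - 1]))
    else:
        t50_0 = float(t[above[0]]) if above.size else float(np.median(t))
    # early-exponential slope of log(A) on points above noise, below half-max
    pos = (a > 0.05 * K0) & (a < 0.8 * K0)
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(a[pos]), 1)[0]
        mu0 = float(np.clip(slope, 0.05, MU_MAX_PER_H * 0.9))
    else:
        mu0 = 1.0
    return K0, mu0, t50_0


def fit_growth(points: Sequence[tuple[float, float]], track_id: int = -1) -> GrowthFit:
    """Least-squares logistic fit to an (time_h, area) series.

    Requires >= 5 points with >= 3 distinct positive areas
    (:class:`InsufficientDataError` otherwise). Pre-emergence zero areas are
    legitimate data: they anchor the lag phase. Initialisation: K from the
    max area, t50 from the half-max crossing, mu from the early slope of
    log(A). If the optimiser fails or a box constraint binds
    (K <= 10x max area, mu <= 50/h), the best-effort parameters are
    returned with ``converged=False``.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 5:
        raise InsufficientDataError("need at least 5 (time, area) points")
    t, a = arr[:, 0], arr[:, 1]
    pos = np.unique(a[a > 0])
    if pos.size < 3:
        raise InsufficientDataError("need at least 3 distinct positive areas")

    K0, mu0, t50_0 = _initial_guess(t, a)
    k_hi = K_MAX_FACTOR * float(a.max())
    lo = [1e-12, 1e-6, t.min() - 10 * (t.max() - t.min() + 1)]
    hi = [k_hi, MU_MAX_PER_H, t.max() + 10 * (t.max() - t.min() + 1)]
    p0 = [min(max(K0, lo[0]), k_hi), min(max(mu0, lo[1]), MU_MAX_PER_H), t50_0]
    converged = True
    try:
        popt, _ = curve_fit(
            logistic_area,
            t,
            a,
            p0=p0,
            bounds=(lo, hi),
            jac=_logistic_jac,
            maxfev=5000,
            xtol=1e-10,
        )
    except (RuntimeError, ValueError):
        popt, converged = np.asarray(p0, dtype=float), False
    K, mu, t50 = (float(v) for v in popt)
    # a bound pressed to within 0.1% counts as binding
    if K >= 0.999 * k_hi or mu >= 0.999 * MU_MAX_PER_H:
        converged = False
    resid = a - logistic_area(t, K, mu, t50)
    rss = float(np.dot(resid, resid))
    tss = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -np.inf)
    return GrowthFit(track_id, K, mu, t50, rss, min(r2, 1.0), converged)


def fit_track(
    track: ColonyTrack,
    all_times_h: Sequence[float] | None = None,
    pad_zeros: bool = True,
) -> GrowthFit:
    """Fit the logistic law to one track's recorded areas.

    With ``pad_zeros`` and the full series time axis, frames before the
    track's first detection contribute zero-area points (the colony was
    below the detection limit), anchoring the lag phase; the alternative
    fits the detected points only.
    """
    pts = [(p.time_h, p.area_px2) for p in track.points]
    if pad_zeros and all_times_h is not None and track.points:
        first = track.points[0].frame_index
        pre = [(float(t), 0.0) for i, t in enumerate(all_times_h) if i < first]
        pts = pre + pts
    return fit_growth(pts, track_id=track.track_id)


def classify_cfu_count(
    count: int, valid_range: tuple[int, int] = CFU_VALID_RANGE
) -> tuple[bool, str]:
    """Apply the plate-count validity convention to one CFU count.

    Counts inside the inclusive interval are statistically reliable;
    below it the plate is not representative, above it crowding can
    suppress growth. Returns ``(valid, reason)`` with reason one of
    ``below_range``, ``above_range``, ``none``.
    """
    lo, hi = valid_range
    if count < lo:
        return False, "below_range"
    if count > hi:
        return False, "above_range"
    return True, "none"


def summarize_plate(
    tracks: Sequence[ColonyTrack],
    include_flagged: bool = False,
    valid_range: tuple[int, int] = CFU_VALID_RANGE,
) -> PlateSummary:
    """Count CFU on one plate and apply the 25-250 validity rule.

    A track counts as one CFU when its emergence time is defined. Merged and
    edge tracks are excluded unless ``include_flagged`` (merged colonies
    still count as their distinct pre-merge tracks, since each arose from a
    separate founder). Bounds are inclusive.
    """
    plate_ids = {trk.plate_id for trk in tracks}
    if len(plate_ids) > 1:
        raise ValueError(f"summarize_plate got mixed plate_ids: {sorted(plate_ids)}")
    plate_id = plate_ids.pop() if plate_ids else "plate"

    n_merged = sum(1 for t in tracks if t.status == "merged" and t.emergence_time_h is not None)
    n_edge = sum(1 for t in tracks if t.status == "edge" and t.emergence_time_h is not None)
    count = 0
    for trk in tracks:
        if trk.emergence_time_h is None:
            continue
        if not include_flagged and trk.status in ("merged", "edge"):
            continue
        count += 1
    valid, reason = classify_cfu_count(count, valid_range)
    return PlateSummary(
        plate_id=plate_id,
        cfu_count=count,
        valid=valid,
        invalid_reason=reason,
        n_merged_excluded=0 if include_flagged else n_merged,
        n_edge_excluded=0 if include_flagged else n_edge,
    )
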