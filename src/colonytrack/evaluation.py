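"""Ground-truth benchmarks of the pipeline on synthetic runs.

Each function sets up a seeded synthetic scenario, runs the relevant
pipeline stages on it, and scores the result against the generator's
ground truth. The same functions back both the test suite and the
reproduction script, so the numbers reported by either are produced by
identical code at identical problem sizes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .kinetics import classify_cfu_count, fit_growth, logistic_area
from .pipeline import RunConfig, process_plate, run_pipeline
from .plate_io import plan_layout, split_series
from .synthetic import SceneSpec, simulate_series, single_plate_spec

__all__ = [
    "layout_capacity_a4",
    "validity_bounds",
    "segmentation_count_accuracy",
    "tracking_identity_fraction",
    "lag_recovery",
    "logistic_recovery_noiseless",
    "logistic_recovery_noisy",
    "pipeline_determinism",
]

#: scan bed of the reference flatbed scanner (mm) and 3-inch dish diameter
A4_BED_MM = (216.0, 297.0)
PLATE_DIAMETER_MM = 76.2


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def layout_capacity_a4() -> int:
    """How many 3-inch plates the grid planner fits on the A4-class bed."""
    return len(plan_layout(*A4_BED_MM, PLATE_DIAMETER_MM))


def validity_bounds(n_max: int = 10_000) -> tuple[int, int, bool]:
    """Exhaustively sweep CFU counts 0..n_max through the validity rule.

    Returns (smallest accepted count, largest accepted count, contiguous)
    where ``contiguous`` is True when the accepted set is exactly one
    unbroken integer interval.
    """
    accepted = [n for n in range(n_max + 1) if classify_cfu_count(n)[0]]
    if not accepted:
        return -1, -1, False
    contiguous = accepted == list(range(accepted[0], accepted[-1] + 1))
    return accepted[0], accepted[-1], contiguous


def _count_spec(seed: int, n_colonies: int) -> SceneSpec:
    # sparse, high-contrast, well-separated colonies rendered at a late
    # frame where every colony is comfortably above the detection limit
    return single_plate_spec(
        seed=seed,
        colonies_per_plate=n_colonies,
        lag_h=(0.25, 0.75),
        duration_h=6.0,
        interval_min=180.0,
        min_center_spacing_px=25.0,
        noise_sigma=0.02,
        colony_contrast=0.35,
    )


def segmentation_count_accuracy(n_frames: int = 100, seed: int = 0) -> dict:
    """Detected vs true colony count on seeded single-frame scenes.

    Scenes hold 10-40 non-touching colonies at >= 3 px background
    separation and contrast >= 5x the pixel-noise sigma; only the final
    frame of each short series is scored. Returns the fraction of scenes
    with an exact count match.
    """
    from .segmentation import estimate_background, segment_frame, subtract_background

    rng = np.random.default_rng(seed)
    seeds = _subseeds(seed, n_frames)
    exact = 0
    for s in seeds:
        n_col = int(rng.integers(10, 41))
        spec = _count_spec(s, n_col)
        frames, gt = simulate_series(spec)
        series = split_series(frames, spec.rois())[0]
        img = series.frames[-1].image
        model = estimate_background(img, "surface")
        residual = subtract_background(img, model, "bright")
        _, dets = segment_frame(residual, min_area_px2=5)
        truth = sum(
            1
            for r in gt.frame_records
            if r["frame"] == len(frames) - 1 and r["true_area_px2"] > 0
        )
        if len(dets) == truth:
            exact += 1
    return dict(exact_frames=exact, n_frames=n_frames, accuracy=exact / n_frames)


def _match_to_truth(x: float, y: float, centers: np.ndarray, tol_px: float = 5.0) -> int:
    d2 = (centers[:, 0] - x) ** 2 + (centers[:, 1] - y) ** 2
    i = int(np.argmin(d2))
    return i if d2[i] <= tol_px**2 else -1


def _local_truth_centers(gt, spec: SceneSpec) -> np.ndarray:
    """Colony centres in the plate crop's coordinate frame."""
    from .plate_io import local_roi

    roi = spec.rois()[0]
    loc = local_roi(roi)
    dx = roi.center_x_px - loc.center_x_px
    dy = roi.center_y_px - loc.center_y_px
    return np.array(
        [[c.center_x_px - dx, c.center_y_px - dy] for c in gt.colonies]
    ).reshape(len(gt.colonies), 2)


def tracking_identity_fraction(n_series: int = 50, seed: int = 0) -> dict:
    """Fraction of (track, frame) assignments matching ground truth.

    Each series holds 20-200 slow-growing colonies at >= 10 px spacing
    (centres stay put; areas grow a few px^2 per frame). A track's identity
    is the true colony nearest its first detection; an assignment is
    correct when a point's nearest true colony equals its track's identity.
    """
    rng = np.random.default_rng(seed)
    seeds = _subseeds(seed, n_series)
    cfg = RunConfig(write_masks=False, write_plots=False)
    correct = 0
    total = 0
    for s in seeds:
        n_col = int(rng.integers(20, 201))
        spec = single_plate_spec(
            seed=s,
            colonies_per_plate=n_col,
            lag_h=(0.5, 3.0),
            K_mm2=(0.5, 1.2),
            duration_h=8.0,
            interval_min=30.0,
            min_center_spacing_px=10.0,
        )
        frames, gt = simulate_series(spec)
        series = split_series(frames, spec.rois())[0]
        tracks, _, _, _ = process_plate(series, cfg)
        centers = _local_truth_centers(gt, spec)
        for trk in tracks:
            ident = _match_to_truth(trk.points[0].x_px, trk.points[0].y_px, centers)
            for p in trk.points:
                total += 1
                if ident >= 0 and _match_to_truth(p.x_px, p.y_px, centers) == ident:
                    correct += 1
    return dict(correct=correct, total=total, fraction=correct / total if total else 0.0)


def lag_recovery(n_colonies: int = 100, seed: int = 0) -> dict:
    """Emergence-time recovery under the study cadence.

    Colonies with lag times uniform on 5-8 h are imaged every 15 min; a
    colony is recovered when |estimated - true lag| <= one frame interval
    plus its detection-limit delay: the time its true (rasterised) area
    needs to reach the emergence area floor after the lag, read off the
    generator's per-frame ground truth. Also reports the median estimated
    emergence time.
    """
    per_plate = 50
    n_plates = math.ceil(n_colonies / per_plate)
    seeds = _subseeds(seed, n_plates)
    cfg = RunConfig(write_masks=False, write_plots=False, area_min_px2=5.0)
    interval_h = 15.0 / 60.0
    hits = 0
    total = 0
    est_all: list[float] = []
    for s in seeds:
        spec = single_plate_spec(
            seed=s,
            colonies_per_plate=per_plate,
            lag_h=(5.0, 8.0),
            duration_h=12.0,
            interval_min=15.0,
        )
        frames, gt = simulate_series(spec)
        series = split_series(frames, spec.rois())[0]
        tracks, _, _, _ = process_plate(series, cfg)
        centers = _local_truth_centers(gt, spec)
        best: dict[int, float] = {}
        for trk in tracks:
            if trk.emergence_time_h is None:
                continue
            ident = _match_to_truth(trk.points[0].x_px, trk.points[0].y_px, centers)
            if ident >= 0 and (ident not in best or trk.emergence_time_h < best[ident]):
                best[ident] = trk.emergence_time_h
        area_min = cfg.area_min_px2
        # per colony: first time its true rasterised area reaches the floor
        reach: dict[int, float] = {}
        for r in gt.frame_records:
            cid = r["colony_id"]
            if cid not in reach and r["true_area_px2"] >= area_min:
                reach[cid] = r["time_h"]
        for i, col in enumerate(gt.colonies):
            if total >= n_colonies:
                break
            total += 1
            if i not in best or i not in reach:
                continue
            est = best[i]
            est_all.append(est)
            delay = reach[i] - col.lag_h
            if abs(est - col.lag_h) <= interval_h + delay:
                hits += 1
    return dict(
        recovered=hits,
        n_colonies=total,
        fraction=hits / total if total else 0.0,
        emergence_median_h=float(np.median(est_all)) if est_all else float("nan"),
    )


def logistic_recovery_noiseless() -> dict:
    """Fit noiseless logistic samples (K=500, mu=1.2/h, t50=6 h) on a
    15-min grid over 0-20 h; report the worst relative parameter error."""
    t = np.arange(0, 20.0001, 0.25)
    true = dict(K=500.0, mu=1.2, t50=6.0)
    a = logistic_area(t, true["K"], true["mu"], true["t50"])
    gf = fit_growth(list(zip(t, a)))
    errs = [
        abs(gf.K - true["K"]) / true["K"],
        abs(gf.mu - true["mu"]) / true["mu"],
        abs(gf.t50_h - true["t50"]) / true["t50"],
    ]
    return dict(max_rel_err=float(max(errs)), converged=gf.converged, n=len(t))


def logistic_recovery_noisy(
    n_curves: int = 100, seed: int = 0, noise_sigma_px2: float = 5.0
) -> dict:
    """Median relative error of (K, mu) on noisy logistic curves.

    Additive Gaussian area noise of fixed sigma (default 5 px^2, i.e.
    signal-to-noise well above 10 for the study-range K of 300-800 px^2);
    parameters drawn from the study ranges (mu 0.8-1.5 /h, t50 5-8 h),
    15-min grid over 20 h.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0, 20.0001, 0.25)
    k_errs = []
    mu_errs = []
    for _ in range(n_curves):
        K = rng.uniform(300, 800)
        mu = rng.uniform(0.8, 1.5)
        t50 = rng.uniform(5, 8)
        a = logistic_area(t, K, mu, t50) + rng.normal(0, noise_sigma_px2, t.shape)
        gf = fit_growth(list(zip(t, np.maximum(a, 0.0))))
        k_errs.append(abs(gf.K - K) / K)
        mu_errs.append(abs(gf.mu - mu) / mu)
    return dict(
        median_K_rel_err=float(np.median(k_errs)),
        median_mu_rel_err=float(np.median(mu_errs)),
        n_curves=n_curves,
    )


def pipeline_determinism(tmp_dir, seed: int = 0) -> dict:
    """Run the full pipeline twice on the same synthetic series and compare
    the three CSV outputs byte for byte."""
    from pathlib import Path

    spec = single_plate_spec(
        seed=seed,
        colonies_per_plate=30,
        duration_h=10.0,
        interval_min=30.0,
    )
    frames, _ = simulate_series(spec)
    tmp_dir = Path(tmp_dir)
    outputs = []
    for run_idx in (1, 2):
        out = tmp_dir / f"run{run_idx}"
        cfg = RunConfig(output_dir=str(out), write_masks=False, write_plots=False, seed=seed)
        run_pipeline(cfg, frames=frames)
        outputs.append(out)
    identical = all(
        (outputs[0] / f"{name}.csv").read_bytes() == (outputs[1] / f"{name}.csv").read_bytes()
        for name in ("tracks", "fits", "plate_summary")
    )
    return dict(identical=bool(identical))
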