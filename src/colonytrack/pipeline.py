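"""End-to-end pipeline: frames in, tables/masks/plots/log out.

Ties the stages together: time axis -> plate ROIs -> per-plate splitting ->
background subtraction -> segmentation -> exclusion flags -> tracking ->
merge censoring -> emergence + growth fits -> plate summaries. Every number
in the output tables is produced by the public module functions; the
pipeline only orchestrates and serialises.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinetics import (
    InsufficientDataError,
    assign_emergence,
    default_area_min_px2,
    fit_track,
    summarize_plate,
)
from .plate_io import (
    PlateROI,
    PlateSeries,
    ScanFrame,
    detect_plate_circle,
    load_image,
    parse_time_axis,
    plan_layout,
    rois_from_layout,
    split_series,
)
from .segmentation import estimate_background, flag_exclusions, segment_frame, subtract_background
from .tracking import build_track_table, detect_merges, link_detections

__all__ = ["RunConfig", "run_pipeline", "process_plate", "export_tables"]

logger = logging.getLogger("colonytrack")

FITS_COLUMNS = ["plate_id", "track_id", "lag_h", "K", "mu", "t50", "r2", "converged", "status"]
SUMMARY_COLUMNS = ["plate_id", "cfu_count", "valid", "invalid_reason", "n_merged_excluded", "n_edge_excluded"]


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run; every field has a default."""

    input_dir: str = "."
    file_glob: str = "*.png"
    output_dir: str = "out"
    dpi: float = 100.0
    time_mode: str = "interval"  # interval | pattern
    interval_min: float = 15.0
    time_pattern: str | None = None
    ts_format: str | None = None
    plate_layout: str = "config"  # config | auto | grid
    plate_diameter_mm: float = 76.2
    rois: list[dict] = field(default_factory=list)  # [{plate_id,cx,cy,r}]
    background_mode: str = "surface"
    background_region: tuple[int, int, int, int] | None = None
    polarity: str = "bright"
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_area_px2: int = 5
    connectivity: int = 8
    circularity_min: float = 0.6
    edge_margin_px: float | None = None
    max_disp_px: float | None = None
    max_misses: int = 2
    area_min_px2: float | None = None  # None -> detection-limit default
    persist_frames: int = 2
    fit_pad_zeros: bool = True
    include_flagged: bool = False
    write_masks: bool = True
    write_plots: bool = True
    write_spreadsheet: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.background_region is not None:
            cfg.background_region = tuple(cfg.background_region)  # type: ignore[assignment]
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        if data.get("background_region") is not None:
            data["background_region"] = list(data["background_region"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _resolve_rois(cfg: RunConfig, first: ScanFrame) -> list[PlateROI]:
    px = 25.4 / cfg.dpi
    if cfg.plate_layout == "config":
        if not cfg.rois:
            # whole frame treated as a single centred plate
            h, w = first.image.shape
            r = min(h, w) / 2.0
            return [PlateROI("plate1", w / 2.0, h / 2.0, r, px)]
        return [
            PlateROI(d["plate_id"], float(d["cx"]), float(d["cy"]), float(d["r"]), px)
            for d in cfg.rois
        ]
    if cfg.plate_layout == "grid":
        h, w = first.image.shape
        centers = plan_layout(w * px, h * px, cfg.plate_diameter_mm)
        return rois_from_layout(centers, cfg.plate_diameter_mm, cfg.dpi)
    if cfg.plate_layout == "auto":
        h, w = first.image.shape
        expected_r = cfg.plate_diameter_mm / 2.0 / px
        centers = plan_layout(w * px, h * px, cfg.plate_diameter_mm)
        rois = []
        for i, (cx_mm, cy_mm) in enumerate(centers):
            hint = (cx_mm / px, cy_mm / px)
            found = detect_plate_circle(
                first.image,
                expected_r,
                tolerance_frac=0.15,
                pixel_size_mm=px,
                plate_id=f"plate{i + 1}",
                hint_center=hint,
                hint_window_px=expected_r / 2.0,
            )
            if found is not None:
                rois.append(found)
            else:
                logger.warning("plate%d: circle not found, using planned position", i + 1)
                rois.extend(rois_from_layout([(cx_mm, cy_mm)], cfg.plate_diameter_mm, cfg.dpi, [f"plate{i + 1}"]))
        return rois
    raise ValueError(f"unknown plate_layout {cfg.plate_layout!r}")


def process_plate(series: PlateSeries, cfg: RunConfig):
    """Run segmentation, tracking and kinetics on one plate series.

    Returns ``(tracks, fits_df, summary, per_frame_masks)``.
    """
    per_frame_dets = []
    per_frame_masks = []
    times = [f.time_h for f in series.frames]
    for frame in series.frames:
        model = estimate_background(frame.image, cfg.background_mode, cfg.background_region)
        residual = subtract_background(frame.image, model, cfg.polarity)
        labels, dets = segment_frame(
            residual,
            frame_index=frame.index,
            threshold_method=cfg.threshold_method,
            fixed_threshold=cfg.fixed_threshold,
            min_area_px2=cfg.min_area_px2,
            connectivity=cfg.connectivity,
        )
        dets = flag_exclusions(
            dets, labels, residual, series.roi, cfg.circularity_min, cfg.edge_margin_px
        )
        logger.debug("plate %s frame %d: %d detections", series.roi.plate_id, frame.index, len(dets))
        per_frame_dets.append(dets)
        per_frame_masks.append(labels)

    tracks = link_detections(
        per_frame_dets,
        times,
        max_disp_px=cfg.max_disp_px,
        max_misses=cfg.max_misses,
        plate_id=series.roi.plate_id,
    )
    tracks = detect_merges(tracks, per_frame_masks)
    area_min = cfg.area_min_px2 if cfg.area_min_px2 is not None else default_area_min_px2(cfg.dpi, cfg.min_area_px2)
    assign_emergence(tracks, area_min, cfg.persist_frames)

    fit_rows = []
    for trk in tracks:
        row = dict(
            plate_id=trk.plate_id,
            track_id=trk.track_id,
            lag_h=trk.emergence_time_h,
            K=np.nan,
            mu=np.nan,
            t50=np.nan,
            r2=np.nan,
            converged=False,
            status=trk.status,
        )
        try:
            gf = fit_track(trk, times, pad_zeros=cfg.fit_pad_zeros)
            row.update(K=gf.K, mu=gf.mu, t50=gf.t50_h, r2=gf.r2, converged=gf.converged)
        except InsufficientDataError:
            pass
        fit_rows.append(row)
    fits = pd.DataFrame(fit_rows, columns=FITS_COLUMNS)
    summary = summarize_plate(tracks, include_flagged=cfg.include_flagged)
    return tracks, fits, summary, per_frame_masks


def export_tables(
    tables: dict[str, pd.DataFrame], out_dir: str | Path, spreadsheet: bool = False
) -> list[Path]:
    """Write tables as canonical CSV (UTF-8, header, '.' decimal), plus an
    optional spreadsheet with one sheet per table mirroring the CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    if spreadsheet:
        xlsx = out_dir / "tables.xlsx"
        with pd.ExcelWriter(xlsx, engine="openpyxl") as writer:
            for name, df in tables.items():
                df.to_excel(writer, sheet_name=name[:31], index=False)
        written.append(xlsx)
    return written


def run_pipeline(cfg: RunConfig, frames: Sequence[ScanFrame] | None = None) -> dict:
    """Execute the full pipeline and write the output bundle.

    ``frames`` may be passed directly (e.g. from the synthetic generator);
    otherwise images matching ``cfg.file_glob`` under ``cfg.input_dir`` are
    loaded with the configured time axis. Writes the track table, fits
    table, plate summary, per-frame 16-bit labelled masks, per-plate
    area-vs-time plots, resolved config and a log file. Returns a dict of
    in-memory results. A plate failing mid-run is logged and skipped; the
    remaining plates still complete.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))
    try:
        logger.info("colonytrack %s starting", __version__)
        if frames is None:
            paths = sorted(Path(cfg.input_dir).glob(cfg.file_glob))
            if not paths:
                raise FileNotFoundError(
                    f"no input frames match {cfg.file_glob!r} in {cfg.input_dir!r}"
                )
            axis = parse_time_axis(
                [p.name for p in paths],
                mode=cfg.time_mode,
                interval_min=cfg.interval_min,
                pattern=cfg.time_pattern,
                ts_format=cfg.ts_format,
            )
            by_name = {p.name: p for p in paths}
            frames = [
                ScanFrame(i, t, load_image(by_name[name]), str(by_name[name]))
                for i, (name, t) in enumerate(axis)
            ]
        if not frames:
            raise FileNotFoundError("no input frames")
        logger.info("%d frames, %.2f h span", len(frames), frames[-1].time_h)

        rois = _resolve_rois(cfg, frames[0])
        logger.info("%d plate ROI(s): %s", len(rois), [r.plate_id for r in rois])
        series_list = split_series(frames, rois)

        all_tracks = []
        fits_frames = []
        summaries = []
        masks_by_plate = {}
        for series in series_list:
            try:
                tracks, fits, summary, masks = process_plate(series, cfg)
            except Exception:  # keep processing the other plates
                logger.exception("plate %s failed", series.roi.plate_id)
                continue
            all_tracks.extend(tracks)
            fits_frames.append(fits)
            summaries.append(summary)
            masks_by_plate[series.roi.plate_id] = masks
            logger.info(
                "plate %s: %d tracks, CFU=%d valid=%s",
                series.roi.plate_id,
                len(tracks),
                summary.cfu_count,
                summary.valid,
            )

        px = 25.4 / cfg.dpi
        track_table = build_track_table(all_tracks, px)
        fits_table = (
            pd.concat(fits_frames, ignore_index=True)
            if fits_frames
            else pd.DataFrame(columns=FITS_COLUMNS)
        )
        fits_table = fits_table.sort_values(["plate_id", "track_id"], kind="stable").reset_index(drop=True)
        summary_table = pd.DataFrame(
            [dataclasses.asdict(s) for s in summaries], columns=SUMMARY_COLUMNS
        )

        tables = {
            "tracks": track_table,
            "fits": fits_table,
            "plate_summary": summary_table,
        }
        export_tables(tables, out_dir, spreadsheet=cfg.write_spreadsheet)

        if cfg.write_masks:
            import tifffile

            mask_dir = out_dir / "masks"
            mask_dir.mkdir(exist_ok=True)
            for pid, masks in masks_by_plate.items():
                for k, m in enumerate(masks):
                    tifffile.imwrite(
                        mask_dir / f"{pid}_frame{k:04d}.tif", m.astype(np.uint16)
                    )
        if cfg.write_plots:
            _write_plots(track_table, out_dir)
        cfg.to_yaml(out_dir / "config_resolved.yaml")
        logger.info("done")
        return dict(
            tracks=all_tracks,
            track_table=track_table,
            fits_table=fits_table,
            summary_table=summary_table,
            masks=masks_by_plate,
            rois=rois,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_plots(track_table: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for pid, sub in track_table.groupby("plate_id"):
        fig, ax = plt.subplots(figsize=(6, 4))
        for _, trk in sub.groupby("track_id"):
            ax.plot(trk["time_h"], trk["area_mm2"], lw=0.8, alpha=0.7)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("colony area (mm$^2$)")
        ax.set_title(f"{pid}: colony area vs time")
        fig.tight_layout()
        fig.savefig(out_dir / f"areas_{pid}.png", dpi=120)
        plt.close(fig)
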