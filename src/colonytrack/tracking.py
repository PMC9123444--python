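"""Link per-frame colony detections into per-colony tracks.

Colonies on agar are effectively stationary: their centroids drift only a
few pixels as the colony grows. Linking is therefore greedy
nearest-centroid matching between consecutive frames, processing candidate
(track, detection) pairs in ascending distance. Detections with no match
start new tracks (colonies emerge mid-series); tracks that miss too many
frames are marked lost. When two tracks collapse onto one connected
component the colonies have merged: both tracks are censored from the merge
frame on, keeping only their unambiguous pre-merge history for kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import Detection

__all__ = ["TrackPoint", "ColonyTrack", "link_detections", "detect_merges", "build_track_table"]

#: fallback linking gate (px) when a frame has no prior detections to scale by
DEFAULT_MAX_DISP_PX = 10.0


@dataclass(frozen=True)
class TrackPoint:
    frame_index: int
    time_h: float
    x_px: float
    y_px: float
    area_px2: float
    label: int
    touching_flag: bool = False
    touches_edge: bool = False


@dataclass
class ColonyTrack:
    """One colony's time series of linked detections."""

    track_id: int
    plate_id: str
    points: list[TrackPoint] = field(default_factory=list)
    status: str = "active"  # active | merged | edge | lost
    emergence_time_h: float | None = None

    @property
    def last_point(self) -> TrackPoint:
        return self.points[-1]

    def times(self) -> np.ndarray:
        return np.array([p.time_h for p in self.points])

    def areas(self) -> np.ndarray:
        return np.array([p.area_px2 for p in self.points])


def _point_from(det: Detection, time_h: float) -> TrackPoint:
    return TrackPoint(
        frame_index=det.frame_index,
        time_h=time_h,
        x_px=det.centroid_x_px,
        y_px=det.centroid_y_px,
        area_px2=det.area_px2,
        label=det.label,
        touching_flag=det.touching_flag,
        touches_edge=det.touches_edge,
    )


def link_detections(
    per_frame_detections: Sequence[Sequence[Detection]],
    times_h: Sequence[float],
    max_disp_px: float | None = None,
    max_misses: int = 2,
    plate_id: str = "plate",
) -> list[ColonyTrack]:
    """Greedy ascending-distance linking of detections across frames.

    For each consecutive frame pair, all (active track, detection) pairs
    within the displacement gate are sorted by distance (ties broken by
    lower (track_id, label)) and matched greedily; each track gains at most
    one detection per frame and vice versa. Unmatched detections seed new
    tracks; a track unmatched in more than ``max_misses`` consecutive frames
    becomes ``lost``. When ``max_disp_px`` is None the gate adapts to 0.5x
    the median equivalent diameter of the previous frame's detections.
    """
    if len(per_frame_detections) != len(times_h):
        raise ValueError("per_frame_detections and times_h must align")
    if max_disp_px is not None and max_disp_px <= 0:
        raise ValueError("max_disp_px must be > 0")

    tracks: list[ColonyTrack] = []
    active: list[ColonyTrack] = []
    next_id = 0
    prev_dets: Sequence[Detection] = []
    misses: dict[int, int] = {}

    for k, (dets, t) in enumerate(zip(per_frame_detections, times_h)):
        if max_disp_px is None:
            if prev_dets:
                gate = 0.5 * float(np.median([d.equivalent_diameter_px for d in prev_dets]))
                gate = max(gate, 2.0)  # sub-pixel colonies still need a workable gate
            else:
                gate = DEFAULT_MAX_DISP_PX
        else:
            gate = max_disp_px

        pairs = []
        if active and dets:
            tx = np.array([[trk.last_point.x_px, trk.last_point.y_px] for trk in active])
            dx = np.array([[det.centroid_x_px, det.centroid_y_px] for det in dets])
            dist = np.hypot(
                tx[:, 0:1] - dx[None, :, 0], tx[:, 1:2] - dx[None, :, 1]
            )
            ii, jj = np.nonzero(dist <= gate)
            pairs = [
                (float(dist[i, j]), active[i].track_id, dets[j].label, active[i], int(j))
                for i, j in zip(ii, jj)
            ]
            pairs.sort(key=lambda p: (p[0], p[1], p[2]))

        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for d, tid, _lab, trk, j in pairs:
            if tid in used_tracks or j in used_dets:
                continue
            trk.points.append(_point_from(dets[j], t))
            misses[tid] = 0
            used_tracks.add(tid)
            used_dets.add(j)

        still_active = []
        for trk in active:
            if trk.track_id in used_tracks:
                still_active.append(trk)
                continue
            misses[trk.track_id] = misses.get(trk.track_id, 0) + 1
            if misses[trk.track_id] > max_misses:
                trk.status = "lost"
            else:
                still_active.append(trk)
        active = still_active

        for j, det in enumerate(dets):
            if j in used_dets:
                continue
            trk = ColonyTrack(next_id, plate_id, [_point_from(det, t)])
            next_id += 1
            misses[trk.track_id] = 0
            tracks.append(trk)
            active.append(trk)
        prev_dets = dets

    return tracks


def detect_merges(
    tracks: Sequence[ColonyTrack],
    per_frame_masks: Sequence[np.ndarray],
) -> list[ColonyTrack]:
    """Mark merged colonies and censor their tracks from the merge frame on.

    A merge at frame k is declared when two or more tracks map onto one
    connected component of frame k's labelled mask (a track with a point at
    k maps via that point's label; a track that lost its detection at k maps
    via its last centroid falling inside a component), or when a
    singly-tracked component carries the fused-blob ``touching_flag``. All
    involved tracks get status ``merged`` with points at or after k removed;
    pre-merge points stay for kinetics. Independently, any track whose
    detection ever touches the plate rim gets status ``edge``.
    """
    tracks = list(tracks)
    n_frames = len(per_frame_masks)
    merged_ids: set[int] = set()

    # points indexed per frame for fast lookup
    pts_at: list[dict[int, TrackPoint]] = [dict() for _ in range(n_frames)]
    for trk in tracks:
        for p in trk.points:
            if p.frame_index < n_frames:
                pts_at[p.frame_index][trk.track_id] = p
    by_id = {trk.track_id: trk for trk in tracks}

    def censor(trk: ColonyTrack, k: int) -> None:
        trk.points = [p for p in trk.points if p.frame_index < k]
        trk.status = "merged"
        merged_ids.add(trk.track_id)

    for k in range(n_frames):
        mask = per_frame_masks[k]
        label_owners: dict[int, set[int]] = {}
        for tid, p in pts_at[k].items():
            if tid in merged_ids:
                continue
            label_owners.setdefault(p.label, set()).add(tid)
        # tracks alive before k whose detection vanished at k: did they fall
        # into a component owned by someone else (i.e. got absorbed)?
        for trk in tracks:
            if trk.track_id in merged_ids or trk.track_id in pts_at[k]:
                continue
            prior = [p for p in trk.points if p.frame_index < k]
            if not prior or trk.status == "lost" and prior[-1].frame_index < k - 1:
                continue
            lp = prior[-1]
            if lp.frame_index < k - 2:  # stale; not a candidate absorption
                continue
            iy, ix = int(round(lp.y_px)), int(round(lp.x_px))
            if 0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1]:
                lab = int(mask[iy, ix])
                if lab > 0:
                    label_owners.setdefault(lab, set()).add(trk.track_id)
        for lab, owners in label_owners.items():
            # a lone track whose component *gains* the fused-blob flag has
            # merged with an untracked neighbour (e.g. a late emerger)
            fused_flag = False
            for tid in owners:
                p = pts_at[k].get(tid)
                if (
                    p is not None
                    and p.label == lab
                    and p.touching_flag
                    and any(not q.touching_flag for q in by_id[tid].points if q.frame_index < k)
                ):
                    fused_flag = True
            if len(owners) >= 2 or fused_flag:
                for tid in owners:
                    censor(by_id[tid], k)

    for trk in tracks:
        if trk.status == "merged":
            continue
        if any(p.touches_edge for p in trk.points):
            trk.status = "edge"
    # a track born inside a merge event can lose every point; drop it
    return [trk for trk in tracks if trk.points]


def build_track_table(
    tracks: Sequence[ColonyTrack], pixel_size_mm: float
) -> pd.DataFrame:
    """Long-format export table: one row per track point.

    Columns: plate_id, track_id, frame, time_h, x_px, y_px, area_px2,
    area_mm2, status; sorted by (plate_id, track_id, frame). Physical area
    is ``area_px2 * pixel_size_mm**2``.
    """
    rows = []
    for trk in tracks:
        for p in trk.points:
            rows.append(
                dict(
                    plate_id=trk.plate_id,
                    track_id=trk.track_id,
                    frame=p.frame_index,
                    time_h=p.time_h,
                    x_px=p.x_px,
                    y_px=p.y_px,
                    area_px2=p.area_px2,
                    area_mm2=p.area_px2 * pixel_size_mm**2,
                    status=trk.status,
                )
            )
    cols = ["plate_id", "track_id", "frame", "time_h", "x_px", "y_px", "area_px2", "area_mm2", "status"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["plate_id", "track_id", "frame"], kind="stable").reset_index(drop=True)
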