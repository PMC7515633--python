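"""Nearest-neighbour nucleus tracking with gap repair and sub-track fusion.

Frame-to-frame linking uses sorted-edge greedy matching: all candidate
pairs within ``max_link_distance`` are sorted by ascending distance
(ties broken by record index order) and accepted greedily, each record
used at most once.  This is order-independent in the two frames and
matches plain nearest-neighbour semantics without the cost model of
optimal assignment.

Two heuristics make tracks more comprehensive, mirroring the emulated
pipeline: single-frame dropouts are repaired by joining a track ending
at frame t to a track starting at frame t+2 (inserting one interpolated
midpoint entry), and remaining sub-tracks are fused end-to-start in the
spatio-temporal domain by the same sorted-greedy rule, interpolating
any skipped frames.  Interpolated entries are flagged and excluded from
speed estimates by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .records import Track


@dataclass
class TrackingParams:
    """Distance/gap thresholds (µm, frames) for linking and repair."""

    max_link_distance: float = 5.0
    gap_max: int = 1  # dropouts longer than this are left to fusion
    gap_link_distance: float = 8.0
    fuse_start_end_distance: float = 8.0
    fuse_max_frame_gap: int = 5

    def validate(self) -> None:
        if min(self.max_link_distance, self.gap_link_distance, self.fuse_start_end_distance) < 0:
            raise ValueError("distances must be >= 0")
        if self.gap_max < 0 or self.fuse_max_frame_gap < 0:
            raise ValueError("frame gaps must be >= 0")


def _positions(frame: pd.DataFrame) -> np.ndarray:
    return frame[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)


def link_frames(
    frame_t: pd.DataFrame, frame_t1: pd.DataFrame, max_link_distance: float
) -> list[tuple[int, int]]:
    """One-to-one assignment between two frames' records.

    Returns (row index in frame_t, row index in frame_t1) pairs.
    Candidate pairs within ``max_link_distance`` are accepted in order
    of ascending distance, each record used at most once; unmatched
    records implicitly terminate or start tracks.
    """
    if len(frame_t) == 0 or len(frame_t1) == 0:
        return []
    pa, pb = _positions(frame_t), _positions(frame_t1)
    pairs = cKDTree(pa).query_ball_tree(cKDTree(pb), r=max_link_distance)
    edges = []
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(pa[i] - pb[j]))
            edges.append((d, i, j))
    edges.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    assignment = []
    for _, i, j in edges:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        assignment.append((i, j))
    return assignment


def build_tracks(nuclei: pd.DataFrame, params: TrackingParams) -> list[Track]:
    """Chain per-frame detections into raw tracks by frame-to-frame linking."""
    params.validate()
    if len(nuclei) == 0:
        return []
    frames = sorted(nuclei["frame"].unique())
    tables = {f: nuclei[nuclei["frame"] == f].reset_index(drop=True) for f in frames}

    open_tracks: dict[int, tuple[list[int], list[np.ndarray]]] = {}
    finished: list[Track] = []
    next_tid = 0

    prev_frame = frames[0]
    prev_table = tables[prev_frame]
    row_track = {}  # row index in prev_table -> open track id
    for i in range(len(prev_table)):
        open_tracks[next_tid] = ([prev_frame], [_positions(prev_table)[i]])
        row_track[i] = next_tid
        next_tid += 1

    for f in frames[1:]:
        cur_table = tables[f]
        assignment = link_frames(prev_table, cur_table, params.max_link_distance)
        matched_prev = {i for i, _ in assignment}
        new_row_track = {}
        cur_pos = _positions(cur_table)
        for i, j in assignment:
            tid = row_track[i]
            open_tracks[tid][0].append(f)
            open_tracks[tid][1].append(cur_pos[j])
            new_row_track[j] = tid
        # Unmatched previous records end their tracks.
        for i, tid in row_track.items():
            if i not in matched_prev:
                fr, pos = open_tracks.pop(tid)
                finished.append(Track(track_id=tid, frames=fr, positions=np.array(pos)))
        # Unmatched current records start new tracks.
        for j in range(len(cur_table)):
            if j not in new_row_track:
                open_tracks[next_tid] = ([f], [cur_pos[j]])
                new_row_track[j] = next_tid
                next_tid += 1
        prev_table, row_track = cur_table, new_row_track

    for tid, (fr, pos) in open_tracks.items():
        finished.append(Track(track_id=tid, frames=fr, positions=np.array(pos)))
    finished.sort(key=lambda t: t.track_id)
    return finished


def repair_single_frame_gaps(tracks: list[Track], params: TrackingParams) -> list[Track]:
    """Join a track ending at frame t with one starting at frame t+2.

    Endpoints must lie within ``gap_link_distance``; one interpolated
    entry at the endpoint midpoint is inserted at frame t+1.  Pairs are
    chosen by the sorted-greedy rule.  Disabled if ``gap_max`` is 0.
    """
    params.validate()
    if params.gap_max < 1:
        return tracks
    return _join_tracks(
        tracks,
        max_frame_gap=2,
        min_frame_gap=2,
        max_distance=params.gap_link_distance,
    )


def fuse_subtracks(tracks: list[Track], params: TrackingParams) -> list[Track]:
    """Fuse sub-tracks end-to-start in the spatio-temporal domain.

    A track end is matched to a strictly later track start within
    ``fuse_start_end_distance`` µm and ``fuse_max_frame_gap`` frames by
    the sorted-greedy rule; matched pairs are concatenated (skipped
    frames linearly interpolated and flagged) and the provenance lists
    the fused source ids.  Chains (A to B to C) collapse into one track.
    """
    params.validate()
    return _join_tracks(
        tracks,
        max_frame_gap=params.fuse_max_frame_gap + 1,
        min_frame_gap=1,
        max_distance=params.fuse_start_end_distance,
    )


def _join_tracks(
    tracks: list[Track],
    max_frame_gap: int,
    min_frame_gap: int,
    max_distance: float,
) -> list[Track]:
    """Greedy end-to-start joining with linear interpolation of skipped frames."""
    n = len(tracks)
    edges = []
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            dt = tracks[b].start_frame - tracks[a].end_frame
            if not (min_frame_gap <= dt <= max_frame_gap):
                continue
            d = float(np.linalg.norm(tracks[a].positions[-1] - tracks[b].positions[0]))
            if d <= max_distance:
                edges.append((d, tracks[a].track_id, tracks[b].track_id, a, b))
    edges.sort()
    succ: dict[int, int] = {}
    pred: dict[int, int] = {}
    for _, _, _, a, b in edges:
        if a in succ or b in pred:
            continue
        succ[a] = b
        pred[b] = a

    out: list[Track] = []
    for a in range(n):
        if a in pred:
            continue  # not a chain head
        frames = list(tracks[a].frames)
        positions = list(tracks[a].positions)
        flags = list(tracks[a].flags)
        provenance = list(tracks[a].provenance) or [tracks[a].track_id]
        cur = a
        while cur in succ:
            nxt = succ[cur]
            gap_frames = range(frames[-1] + 1, tracks[nxt].start_frame)
            p0, p1 = positions[-1], tracks[nxt].positions[0]
            f0, f1 = frames[-1], tracks[nxt].start_frame
            for g in gap_frames:
                w = (g - f0) / (f1 - f0)
                frames.append(g)
                positions.append((1 - w) * np.asarray(p0) + w * np.asarray(p1))
                flags.append("interpolated")
            frames.extend(tracks[nxt].frames)
            positions.extend(tracks[nxt].positions)
            flags.extend(tracks[nxt].flags)
            provenance.extend(tracks[nxt].provenance or [tracks[nxt].track_id])
            cur = nxt
        out.append(
            Track(
                track_id=tracks[a].track_id,
                frames=np.array(frames),
                positions=np.array(positions),
                flags=flags,
                provenance=provenance if len(provenance) > 1 else list(tracks[a].provenance),
            )
        )
    out.sort(key=lambda t: t.track_id)
    return out


def track_nuclei(nuclei: pd.DataFrame, params: TrackingParams) -> list[Track]:
    """Full tracking pass: link, repair single-frame gaps, fuse sub-tracks."""
    tracks = build_tracks(nuclei, params)
    tracks = repair_single_frame_gaps(tracks, params)
    tracks = fuse_subtracks(tracks, params)
    for t in tracks:
        assert not t.has_gaps(), f"track {t.track_id} has internal gaps after repair"
    return tracks


def estimate_mean_speed(
    tracks: list[Track],
    window: int,
    frame_interval: float,
    include_interpolated: bool = False,
) -> float:
    """Mean migration speed (µm/min) over a fixed window of steps.

    ``window`` is the number of displacement steps taken per track, so
    every selected track must span at least ``window + 1`` frames (the
    inclusion rule: only cells trackable over the entire time window
    enter the estimate).  The estimate is the arithmetic mean of all
    per-step displacement lengths of all selected tracks, divided by
    ``frame_interval``.  Interpolated entries are excluded unless
    ``include_interpolated`` is set (their steps are skipped).
    """
    if window < 1:
        raise ValueError("window must be >= 1 step")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    if not tracks:
        raise ValueError("no tracks selected")
    steps: list[float] = []
    for t in tracks:
        if len(t) < window + 1:
            raise ValueError(
                f"track {t.track_id} spans {len(t)} frames, "
                f"shorter than the {window + 1}-frame window"
            )
        pos = t.positions[: window + 1]
        obs = t.observed_mask()[: window + 1]
        disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        if not include_interpolated:
            ok = obs[:-1] & obs[1:]
            disp = disp[ok]
        steps.extend(disp)
    if not steps:
        raise ValueError("no displacement steps available")
    return float(np.mean(steps) / frame_interval)
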