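"""Frame-to-frame linking of localizations into microbubble tracks.

Linking is a gated minimum-total-distance one-to-one assignment (Hungarian
algorithm) between consecutive frames; there is no gap closing, so a
missed detection splits a track.  Tracks are Savitzky–Golay smoothed,
length-filtered (tracks with fewer than ten positions discarded by
default), and per-segment speeds and signed axial velocity components are
computed from consecutive smoothed positions times the frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.signal import savgol_filter

from .localize import Localization

__all__ = [
    "TrackConfig",
    "Track",
    "link_frames",
    "build_tracks",
    "smooth_track",
    "filter_tracks",
    "track_velocities",
    "link_tracks",
    "tracks_to_frame",
    "read_tracks",
    "write_tracks",
]

_FORBIDDEN = 1e12  # cost placeholder for pairs beyond the gate


@dataclass(frozen=True)
class TrackConfig:
    """Linking gate, minimum length and smoothing parameters.

    The default gate corresponds to a 100 mm/s maximum detectable speed at
    500 volumes/s (the gate directly bounds the fastest recoverable flow).
    """

    max_link_distance_mm: float = 100.0 / 500.0
    min_track_length: int = 10
    sg_window: int = 5
    sg_order: int = 2
    smooth_for_velocity: bool = True

    def __post_init__(self) -> None:
        if self.max_link_distance_mm <= 0:
            raise ValueError("max_link_distance_mm must be positive")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")


@dataclass
class Track:
    """One linked bubble trajectory over strictly consecutive frames."""

    track_id: int
    frames: np.ndarray           # (n,) strictly increasing by 1
    positions_mm: np.ndarray     # (n, 3) raw localized positions
    smoothed_mm: np.ndarray | None = None
    speeds_mm_s: np.ndarray | None = None   # (n-1,)
    vz_mm_s: np.ndarray | None = None       # (n-1,) signed axial component

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_mm = np.atleast_2d(np.asarray(self.positions_mm, dtype=float))
        if len(self.frames) != self.positions_mm.shape[0]:
            raise ValueError("frames and positions length mismatch")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("track frames must be strictly consecutive")

    def __len__(self) -> int:
        return len(self.frames)


def link_frames(
    pos_a: np.ndarray, pos_b: np.ndarray, max_link_distance_mm: float
) -> list[tuple[int, int]]:
    """Optimal gated one-to-one pairing between two detection sets.

    Returns index pairs (i in a, j in b) with pairwise distance within the
    gate, minimizing total Euclidean distance among admissible pairings.
    Detections left unpaired terminate or start tracks.
    """
    pos_a = np.atleast_2d(np.asarray(pos_a, dtype=float))
    pos_b = np.atleast_2d(np.asarray(pos_b, dtype=float))
    if pos_a.size == 0 or pos_b.size == 0:
        return []
    dist = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=2)
    cost = np.where(dist <= max_link_distance_mm, dist, _FORBIDDEN)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if dist[i, j] <= max_link_distance_mm]


def build_tracks(locs: list[Localization], config: TrackConfig | None = None) -> list[Track]:
    """Chain frame-to-frame assignments into tracks (raw positions only)."""
    if config is None:
        config = TrackConfig()
    if not locs:
        return []
    by_frame: dict[int, list[Localization]] = {}
    for l in locs:
        by_frame.setdefault(l.frame, []).append(l)
    frames_sorted = sorted(by_frame)

    next_id = 0
    open_tracks: dict[int, dict] = {}  # index in current frame -> {'id', 'frames', 'pos'}
    done: list[Track] = []

    prev_frame = None
    prev_locs: list[Localization] = []
    for frame in frames_sorted:
        cur_locs = by_frame[frame]
        cur_pos = np.array([l.position_mm for l in cur_locs])
        carried: dict[int, dict] = {}
        if prev_frame is not None and frame == prev_frame + 1 and open_tracks:
            prev_pos = np.array([l.position_mm for l in prev_locs])
            pairs = link_frames(prev_pos, cur_pos, config.max_link_distance_mm)
            matched_prev = set()
            for i, j in pairs:
                if i in open_tracks:
                    tr = open_tracks[i]
                    tr["frames"].append(frame)
                    tr["pos"].append(cur_pos[j])
                    carried[j] = tr
                    matched_prev.add(i)
            for i, tr in open_tracks.items():
                if i not in matched_prev:
                    done.append(Track(tr["id"], tr["frames"], np.array(tr["pos"])))
        else:
            for tr in open_tracks.values():
                done.append(Track(tr["id"], tr["frames"], np.array(tr["pos"])))
        for j, l in enumerate(cur_locs):
            if j not in carried:
                carried[j] = {"id": next_id, "frames": [frame], "pos": [np.asarray(l.position_mm)]}
                next_id += 1
        open_tracks = carried
        prev_frame = frame
        prev_locs = cur_locs
    for tr in open_tracks.values():
        done.append(Track(tr["id"], tr["frames"], np.array(tr["pos"])))
    done.sort(key=lambda t: t.track_id)
    return done


def smooth_track(track: Track, sg_window: int = 5, sg_order: int = 2) -> Track:
    """Savitzky–Golay smooth each coordinate; short tracks pass through."""
    if len(track) < sg_window:
        track.smoothed_mm = track.positions_mm.copy()
    else:
        track.smoothed_mm = savgol_filter(
            track.positions_mm, window_length=sg_window, polyorder=sg_order, axis=0
        )
    return track


def filter_tracks(tracks: list[Track], min_track_length: int = 10) -> list[Track]:
    """Drop tracks with fewer than ``min_track_length`` positions.

    'Below ten positions' is read strictly: a 10-point track is kept.
    """
    return [t for t in tracks if len(t) >= min_track_length]


def track_velocities(track: Track, frame_rate: float, use_smoothed: bool = True) -> Track:
    """Per-segment speed and signed axial velocity.

    speed_i = ‖p_{i+1} − p_i‖ × frame_rate (mm/s);
    vz_i = (z_{i+1} − z_i) × frame_rate, signed.
    """
    if len(track) < 2:
        raise ValueError("velocity needs at least 2 positions")
    pos = track.smoothed_mm if (use_smoothed and track.smoothed_mm is not None) else track.positions_mm
    deltas = np.diff(pos, axis=0)
    track.speeds_mm_s = np.linalg.norm(deltas, axis=1) * frame_rate
    track.vz_mm_s = deltas[:, 0] * frame_rate
    return track


def link_tracks(
    locs: list[Localization], frame_rate: float, config: TrackConfig | None = None
) -> list[Track]:
    """Full tracking chain: link → length-filter → smooth → velocities."""
    if config is None:
        config = TrackConfig()
    tracks = build_tracks(locs, config)
    tracks = filter_tracks(tracks, config.min_track_length)
    for t in tracks:
        smooth_track(t, config.sg_window, config.sg_order)
        track_velocities(t, frame_rate, use_smoothed=config.smooth_for_velocity)
    return tracks


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        sm = t.smoothed_mm if t.smoothed_mm is not None else t.positions_mm
        for i, frame in enumerate(t.frames):
            speed = t.speeds_mm_s[i] if (t.speeds_mm_s is not None and i < len(t.speeds_mm_s)) else np.nan
            vz = t.vz_mm_s[i] if (t.vz_mm_s is not None and i < len(t.vz_mm_s)) else np.nan
            rows.append(
                (t.track_id, int(frame), *t.positions_mm[i], *sm[i], speed, vz)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id", "frame", "z_mm", "x_mm", "y_mm",
            "z_smooth", "x_smooth", "y_smooth", "speed_mm_s", "vz_mm_s",
        ],
    )


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    out: list[Track] = []
    for tid, sub in df.groupby("track_id"):
        sub = sub.sort_values("frame")
        t = Track(
            int(tid),
            sub["frame"].to_numpy(),
            sub[["z_mm", "x_mm", "y_mm"]].to_numpy(),
        )
        t.smoothed_mm = sub[["z_smooth", "x_smooth", "y_smooth"]].to_numpy()
        speeds = sub["speed_mm_s"].to_numpy()[:-1]
        vz = sub["vz_mm_s"].to_numpy()[:-1]
        if not np.any(np.isnan(speeds)):
            t.speeds_mm_s, t.vz_mm_s = speeds, vz
        out.append(t)
    return out
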