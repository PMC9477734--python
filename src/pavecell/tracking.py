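"""Linking, speed estimation and motility classification of CESA foci.

CESA foci at the plasma membrane fall into three motility classes:
steadily migrating membrane complexes (CSCs, 25-200 nm/min), immobile
foci (STALLs, < 25 nm/min) and small CESA-containing compartments
(SMACCs) that move fast and erratically (> 200 nm/min).  Because an
immobile focus still shows frame-to-frame jitter from localization
noise, while an erratic walker covers distance without net
displacement, classification uses two complementary speed metrics:

* ``v_fit`` — the absolute slope of a least-squares line through the
  positions projected on the track's principal axis, a *persistent*
  speed robust to jitter;
* ``v_step`` — the mean frame-to-frame step length per unit time, a
  *path* speed sensitive to erratic motion.

A track is a SMACC if ``v_step`` (or ``v_fit``) exceeds 200 nm/min, a
STALL if ``v_fit`` < 25 nm/min, and a CSC otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Track",
    "SpeedCutoffs",
    "link_tracks",
    "track_speed",
    "classify_track",
    "classify_and_fractions",
    "kymograph",
]


@dataclass(frozen=True)
class SpeedCutoffs:
    """Velocity cut-offs (nm/min): STALL < ``stall_max``;
    CSC in [``stall_max``, ``csc_max``]; SMACC > ``csc_max``."""

    stall_max: float = 25.0
    csc_max: float = 200.0

    def __post_init__(self) -> None:
        if not 0 < self.stall_max < self.csc_max:
            raise ValueError("require 0 < stall_max < csc_max")


@dataclass
class Track:
    """Time-linked localizations of one focus.  Positions in px."""

    track_id: int
    frames: np.ndarray  # strictly increasing
    x: np.ndarray
    y: np.ndarray
    v_fit: float | None = None  # nm/min
    v_step: float | None = None  # nm/min
    motility_class: str | None = None

    def __len__(self) -> int:
        return len(self.frames)


def link_tracks(
    spots_by_frame: pd.DataFrame,
    *,
    max_displacement_nm: float = 500.0,
    min_length: int = 4,
    pixel_size_nm: float = 110.0,
    gap_closing: bool = True,
) -> list[Track]:
    """Greedy mutual-nearest-neighbour frame-to-frame linking.

    ``spots_by_frame`` needs columns ``frame, x, y`` (px).  A link is
    accepted only when two detections are each other's nearest
    neighbour in consecutive frames and closer than
    ``max_displacement_nm``; with ``gap_closing`` a track end may
    additionally bridge a single missed frame (at twice the search
    radius).  Tracks shorter than ``min_length`` frames are discarded.
    """
    if len(spots_by_frame) == 0:
        return []
    max_disp_px = max_displacement_nm / pixel_size_nm
    frames = {
        int(f): g[["x", "y"]].to_numpy(dtype=float)
        for f, g in spots_by_frame.groupby("frame")
    }
    frame_ids = sorted(frames)
    # active track: list of (frame, x, y); open_at maps last-frame index
    active: list[list[tuple[int, float, float]]] = []
    finished: list[list[tuple[int, float, float]]] = []
    prev_tracks: dict[int, int] = {}  # detection idx in prev frame -> track idx

    for fi, f in enumerate(frame_ids):
        pts = frames[f]
        assigned = np.zeros(len(pts), dtype=bool)
        new_prev: dict[int, int] = {}
        if fi > 0 and prev_tracks:
            pf = frame_ids[fi - 1]
            prev_pts = frames[pf]
            if len(pts) and len(prev_pts):
                tree_cur = cKDTree(pts)
                tree_prev = cKDTree(prev_pts)
                d_fwd, nn_fwd = tree_cur.query(prev_pts)  # prev -> cur
                d_bwd, nn_bwd = tree_prev.query(pts)  # cur -> prev
                for pi, ti in prev_tracks.items():
                    ci = nn_fwd[pi]
                    if d_fwd[pi] <= max_disp_px * (f - pf) and nn_bwd[ci] == pi:
                        if not assigned[ci]:
                            active[ti].append((f, float(pts[ci, 0]), float(pts[ci, 1])))
                            assigned[ci] = True
                            new_prev[ci] = ti
        # optional one-frame gap closing for tracks that missed this round
        if gap_closing and fi > 1:
            stale = [
                ti for ti in range(len(active))
                if active[ti] and active[ti][-1][0] == frame_ids[fi - 2]
                and ti not in new_prev.values()
            ]
            if stale and np.any(~assigned):
                free = np.nonzero(~assigned)[0]
                tree_free = cKDTree(pts[free])
                for ti in stale:
                    _, lx, ly = active[ti][-1]
                    d, j = tree_free.query([lx, ly])
                    ci = free[j]
                    if d <= 2 * max_disp_px and not assigned[ci]:
                        active[ti].append((f, float(pts[ci, 0]), float(pts[ci, 1])))
                        assigned[ci] = True
                        new_prev[ci] = ti
        # unassigned detections start new tracks
        for ci in np.nonzero(~assigned)[0]:
            active.append([(f, float(pts[ci, 0]), float(pts[ci, 1]))])
            new_prev[ci] = len(active) - 1
        prev_tracks = new_prev

    finished.extend(t for t in active if t)
    tracks = []
    tid = 0
    for pts_list in finished:
        if len(pts_list) < min_length:
            continue
        arr = np.array(pts_list)
        tracks.append(
            Track(tid, arr[:, 0].astype(int), arr[:, 1].copy(), arr[:, 2].copy())
        )
        tid += 1
    return tracks


def track_speed(
    track: Track, pixel_size_nm: float = 110.0, interval_s: float = 60.0
) -> tuple[float, float]:
    """Persistent and path speed of a track, both in nm/min.

    ``v_fit``: positions are projected on the principal axis (first
    right-singular vector of the centred coordinates) and regressed
    against time; the absolute slope is the persistent speed.
    ``v_step``: mean frame-to-frame displacement divided by the frame
    interval.  Both are invariant to global translation and to
    time-reversal of the track.
    """
    if len(track) < 4:
        raise ValueError("track_speed needs >= 4 frames")
    pos_nm = np.column_stack([track.x, track.y]) * pixel_size_nm
    t_min = track.frames * interval_s / 60.0
    centred = pos_nm - pos_nm.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    proj = centred @ vt[0]
    slope = np.polyfit(t_min, proj, 1)[0]
    v_fit = float(abs(slope))
    steps = np.linalg.norm(np.diff(pos_nm, axis=0), axis=1)
    dt = np.diff(t_min)
    v_step = float(np.mean(steps / dt))
    track.v_fit, track.v_step = v_fit, v_step
    return v_fit, v_step


def classify_track(v_fit: float, v_step: float, cutoffs: SpeedCutoffs = SpeedCutoffs()) -> str:
    """Apply the velocity cut-offs: SMACC if the path speed (or the
    persistent speed) exceeds ``csc_max``; else STALL if the persistent
    speed is below ``stall_max``; else CSC."""
    if v_step > cutoffs.csc_max or v_fit > cutoffs.csc_max:
        return "SMACC"
    if v_fit < cutoffs.stall_max:
        return "STALL"
    return "CSC"


def classify_and_fractions(
    tracks: list[Track],
    cutoffs: SpeedCutoffs = SpeedCutoffs(),
    *,
    pixel_size_nm: float = 110.0,
    interval_s: float = 60.0,
) -> tuple[list[Track], dict[str, float]]:
    """Classify every track and return the population fractions.

    Fractions sum to 1 whenever tracks exist; an empty track list
    raises, since fractions are undefined.
    """
    if not tracks:
        raise ValueError("no tracks: class fractions are undefined")
    counts = {"CSC": 0, "STALL": 0, "SMACC": 0}
    for tr in tracks:
        if tr.v_fit is None or tr.v_step is None:
            track_speed(tr, pixel_size_nm, interval_s)
        tr.motility_class = classify_track(tr.v_fit, tr.v_step, cutoffs)
        counts[tr.motility_class] += 1
    n = len(tracks)
    return tracks, {k: v / n for k, v in counts.items()}


def kymograph(
    timelapse: np.ndarray,
    polyline: np.ndarray,
    line_width_px: int = 1,
    *,
    sample_spacing_px: float = 1.0,
) -> np.ndarray:
    """Distance-time image sampled along a polyline.

    Intensity is interpolated along the polyline for every frame
    (averaged across ``line_width_px`` perpendicular offsets) and the
    per-frame profiles are stacked into a ``(n_samples, n_frames)``
    image: a mover at speed v traces a line of slope v.
    """
    from scipy.ndimage import map_coordinates

    pl = np.asarray(polyline, dtype=float)
    if pl.ndim != 2 or len(pl) < 2:
        raise ValueError("polyline needs at least 2 vertices")
    seg = np.diff(pl, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = seg_len.sum()
    if total == 0:
        raise ValueError("degenerate (zero-length) polyline")
    n_samples = max(int(np.ceil(total / sample_spacing_px)) + 1, 2)
    s = np.linspace(0, total, n_samples)
    cum = np.concatenate([[0], np.cumsum(seg_len)])
    xs = np.interp(s, cum, pl[:, 0])
    ys = np.interp(s, cum, pl[:, 1])
    # unit normals per sample for line-width averaging
    dx = np.gradient(xs)
    dy = np.gradient(ys)
    norm = np.hypot(dx, dy)
    norm[norm == 0] = 1.0
    nx_, ny_ = -dy / norm, dx / norm
    offsets = np.arange(line_width_px) - (line_width_px - 1) / 2.0

    movie = np.asarray(timelapse, dtype=float)
    out = np.zeros((n_samples, movie.shape[0]))
    for t in range(movie.shape[0]):
        acc = np.zeros(n_samples)
        for o in offsets:
            coords = np.vstack([ys + o * ny_, xs + o * nx_])
            acc += map_coordinates(movie[t], coords, order=1, mode="nearest")
        out[:, t] = acc / len(offsets)
    return out
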