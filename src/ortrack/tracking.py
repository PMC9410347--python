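"""Monocular tracking: link one camera's filtered detections into
ground-plane tracklets.

The linker is deliberately simple — the goal is tracklets that are rarely
wrong rather than maximally complete, because broken tracklets are
repaired downstream during cross-camera re-identification.  Per frame, a
detection may extend an existing track only if its ground-plane
displacement from the track's last observed point is within the gate T13
(default 40 cm, about one adult step); competing candidates are resolved
by a minimum-total-distance one-to-one assignment.  A track that goes
unobserved survives for up to T14 frames (default 60, one second at
60 FPS) before it is closed, which bridges short detector dropouts
without any motion model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .appearance import mean_histogram
from .detection_io import Detection
from .geometry import (GroundPoint, Homography, ImagePoint, apply_homography,
                       foot_location)


@dataclass
class Trajectory:
    """A per-camera tracklet: an ordered frame -> ground-point map.

    Gaps (frames with no observation between first_frame and last_frame)
    are allowed; observed_length counts only observed frames.
    """

    camera_id: str
    local_id: int
    points: dict[int, GroundPoint] = field(default_factory=dict)
    detections: dict[int, Detection] = field(default_factory=dict)
    mean_histogram: Optional[np.ndarray] = None

    @property
    def first_frame(self) -> int:
        return min(self.points)

    @property
    def last_frame(self) -> int:
        return max(self.points)

    @property
    def observed_length(self) -> int:
        return len(self.points)

    @property
    def frames(self) -> list[int]:
        return sorted(self.points)

    def add(self, frame: int, point: GroundPoint, det: Optional[Detection] = None) -> None:
        if frame in self.points:
            raise ValueError(f"trajectory {self.camera_id}/{self.local_id} "
                             f"already has an observation at frame {frame}")
        self.points[frame] = point
        if det is not None:
            self.detections[frame] = det

    def finalize_histogram(self) -> None:
        self.mean_histogram = mean_histogram(
            [d.histogram for d in self.detections.values()])


@dataclass(frozen=True)
class TrackerConfig:
    """T13: displacement gate in cm (default 40, one step length).
    T14: memory window in frames (default 60, one second at 60 FPS) — how
    long a disappeared track keeps its identity before being closed.
    scale_gate_with_gap: experimental option multiplying the gate by the
    number of frames since the track was last observed."""

    T13: float = 40.0
    T14: int = 60
    scale_gate_with_gap: bool = False

    def __post_init__(self) -> None:
        if self.T13 <= 0:
            raise ValueError("T13 must be > 0")
        if self.T14 < 0:
            raise ValueError("T14 must be >= 0")


def localize_frame(
    dets: Sequence[Detection], H: Homography
) -> list[tuple[GroundPoint, Detection]]:
    """Map each detection's ankle midpoint onto the ground plane."""
    out = []
    for d in dets:
        foot = foot_location(ImagePoint(*d.left_ankle), ImagePoint(*d.right_ankle))
        out.append((apply_homography(H, foot), d))
    return out


def localize_detections(
    dets: Sequence[Detection], H: Homography
) -> dict[int, list[tuple[GroundPoint, Detection]]]:
    """Group detections by frame and localize each frame."""
    frames: dict[int, list[Detection]] = {}
    for d in dets:
        frames.setdefault(d.frame, []).append(d)
    return {f: localize_frame(ds, H) for f, ds in sorted(frames.items())}


# Cost-matrix padding for gated assignment: any forbidden pairing must be
# more expensive than every feasible full assignment combined.
def _gated_assignment(cost: np.ndarray, feasible: np.ndarray) -> list[tuple[int, int]]:
    """Maximum-cardinality, minimum-total-cost one-to-one assignment over
    the feasible pairs.  Near-ties are broken toward low (row, column)
    index by an infinitesimal lexicographic perturbation."""
    n, m = cost.shape
    if n == 0 or m == 0 or not feasible.any():
        return []
    big = cost[feasible].sum() + cost[feasible].max() * (min(n, m) + 1) + 1.0
    c = np.where(feasible, cost, big)
    # deterministic tie-break: prefer earlier tracks / earlier detections
    scale = max(c[feasible].max(), 1.0)
    eps = 1e-9 * scale / (n * m + 1)
    idx = np.arange(n)[:, None] * m + np.arange(m)[None, :]
    c = c + eps * idx
    rows, cols = linear_sum_assignment(c)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if feasible[i, j]]


class _ActiveTrack:
    __slots__ = ("traj", "last_frame", "last_point")

    def __init__(self, traj: Trajectory, frame: int, point: GroundPoint):
        self.traj = traj
        self.last_frame = frame
        self.last_point = point


def link_tracks(
    localized: dict[int, list[tuple[GroundPoint, Detection]]],
    cfg: TrackerConfig,
    camera_id: str = "",
) -> list[Trajectory]:
    """Frame-by-frame linking of localized detections into trajectories.

    Active tracks are those observed within the last T14 frames.  Each
    frame, (track, detection) pairs whose ground distance is within T13
    form a bipartite graph; a minimum-total-distance one-to-one assignment
    extends tracks, unassigned detections open new tracks, and tracks
    unobserved for more than T14 frames are closed.  Every detection ends
    up in exactly one trajectory; local ids follow track creation order.
    """
    frames = list(localized.keys())
    if frames != sorted(frames):
        raise ValueError("localized frames must be sorted ascending")

    active: list[_ActiveTrack] = []
    done: list[Trajectory] = []
    next_id = 0

    for frame in frames:
        # expire tracks silent for more than T14 frames
        still = []
        for t in active:
            if frame - t.last_frame - 1 > cfg.T14:
                done.append(t.traj)
            else:
                still.append(t)
        active = still

        items = localized[frame]
        if not items:
            continue
        pts = np.array([[gp.X, gp.Y] for gp, _ in items])
        assigned_dets: set[int] = set()
        if active:
            ref = np.array([[t.last_point.X, t.last_point.Y] for t in active])
            cost = np.linalg.norm(ref[:, None, :] - pts[None, :, :], axis=2)
            if cfg.scale_gate_with_gap:
                gaps = np.array([frame - t.last_frame for t in active], dtype=float)
                gate = cfg.T13 * gaps[:, None]
            else:
                gate = cfg.T13
            feasible = cost <= gate
            for ti, di in _gated_assignment(cost, feasible):
                gp, det = items[di]
                tr = active[ti]
                tr.traj.add(frame, gp, det)
                tr.last_frame = frame
                tr.last_point = gp
                assigned_dets.add(di)
        for di, (gp, det) in enumerate(items):
            if di in assigned_dets:
                continue
            cam = camera_id or (det.camera_id if det is not None else "")
            traj = Trajectory(camera_id=cam, local_id=next_id)
            next_id += 1
            traj.add(frame, gp, det)
            active.append(_ActiveTrack(traj, frame, gp))

    done.extend(t.traj for t in active)
    done.sort(key=lambda t: t.local_id)
    for t in done:
        t.finalize_histogram()
    return done


def track_camera(
    dets: Sequence[Detection], H: Homography, cfg: TrackerConfig, camera_id: str = ""
) -> list[Trajectory]:
    """Convenience: localize then link one camera's filtered detections."""
    return link_tracks(localize_detections(dets, H), cfg,
                       camera_id=camera_id or (dets[0].camera_id if dets else ""))


# ---------------------------------------------------------------------------
# Trajectory CSV: one row per observed frame.

def trajectories_to_frame_table(
    trajectories: Iterable[Trajectory],
    global_ids: Optional[dict[tuple[str, int], int]] = None,
) -> pd.DataFrame:
    rows = []
    for t in trajectories:
        gid = None if global_ids is None else global_ids[(t.camera_id, t.local_id)]
        for f in t.frames:
            p = t.points[f]
            row = {"camera_id": t.camera_id, "local_id": t.local_id,
                   "frame": f, "X_cm": p.X, "Y_cm": p.Y}
            if gid is not None:
                row["global_id"] = gid
            rows.append(row)
    cols = ["camera_id", "local_id", "frame", "X_cm", "Y_cm"]
    if global_ids is not None:
        cols.insert(2, "global_id")
    return pd.DataFrame(rows, columns=cols)


def write_trajectories(trajectories: Iterable[Trajectory], path: str | Path,
                       global_ids: Optional[dict[tuple[str, int], int]] = None) -> None:
    trajectories_to_frame_table(trajectories, global_ids).to_csv(
        path, index=False, float_format="%.9f")


def read_trajectories(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path, dtype={"camera_id": str})
    out = []
    for (cam, lid), grp in df.groupby(["camera_id", "local_id"], sort=True):
        t = Trajectory(camera_id=str(cam), local_id=int(lid))
        for _, r in grp.sort_values("frame").iterrows():
            t.add(int(r["frame"]), GroundPoint(float(r["X_cm"]), float(r["Y_cm"])))
        out.append(t)
    return out
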