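"""3-D trajectory visualization: (X, Y, frame) colored by identity."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .tracking import Trajectory


def plot_trajectories_3d(
    trajectories: Iterable[Trajectory],
    global_ids: Optional[Mapping[tuple[str, int], int]] = None,
    title: str = "",
    ax: Optional[plt.Axes] = None,
):
    """Plot trajectories as 3-D polylines over (X, Y, frame).

    With `global_ids` the color encodes the cross-camera identity;
    otherwise each tracklet gets its own color.
    """
    if ax is None:
        fig = plt.figure(figsize=(7, 6))
        ax = fig.add_subplot(111, projection="3d")
    cmap = plt.get_cmap("tab10")
    for k, t in enumerate(trajectories):
        cid = global_ids[(t.camera_id, t.local_id)] if global_ids else k
        frames = t.frames
        xs = [t.points[f].X for f in frames]
        ys = [t.points[f].Y for f in frames]
        ax.plot(xs, ys, frames, color=cmap(cid % 10), linewidth=0.8)
    ax.set_xlabel("X (cm)")
    ax.set_ylabel("Y (cm)")
    ax.set_zlabel("frame")
    if title:
        ax.set_title(title)
    return ax


def save_trajectory_plots(
    per_camera: Mapping[str, list[Trajectory]],
    global_ids: Mapping[tuple[str, int], int],
    outdir: str | Path,
    fmt: str = "png",
) -> list[Path]:
    """One 3-D plot per camera plus a merged all-camera plot."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for cam in sorted(per_camera):
        ax = plot_trajectories_3d(per_camera[cam], global_ids, title=cam)
        p = outdir / f"trajectories_{cam}.{fmt}"
        ax.figure.savefig(p, dpi=120)
        plt.close(ax.figure)
        written.append(p)
    merged = [t for cam in sorted(per_camera) for t in per_camera[cam]]
    ax = plot_trajectories_3d(merged, global_ids, title="all cameras")
    p = outdir / f"trajectories_merged.{fmt}"
    ax.figure.savefig(p, dpi=120)
    plt.close(ax.figure)
    written.append(p)
    return written
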