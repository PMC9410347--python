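"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from ortrack.detection_io import Detection, N_KEYPOINTS
from ortrack.geometry import GroundPoint
from ortrack.tracking import Trajectory


def make_detection(
    camera_id: str = "cam0",
    frame: int = 0,
    ankles: tuple[tuple[float, float], tuple[float, float]] = ((100.0, 200.0), (110.0, 200.0)),
    ankle_scores: tuple[float, float] = (0.9, 0.9),
    pose_score: float = 3.0,
    histogram: np.ndarray | None = None,
) -> Detection:
    """A detection with given ankles; the other 15 keypoints are filler."""
    kp = np.zeros((N_KEYPOINTS, 2))
    kp[:15] = (100.0, 100.0)
    kp[15] = ankles[0]
    kp[16] = ankles[1]
    scores = np.full(N_KEYPOINTS, 0.8)
    scores[15], scores[16] = ankle_scores
    return Detection(camera_id=camera_id, frame=frame, keypoints=kp,
                     keypoint_scores=scores, pose_score=pose_score,
                     bbox=(90.0, 50.0, 40.0, 150.0), histogram=histogram)


def make_trajectory(
    camera_id: str,
    local_id: int,
    frames: list[int],
    xy: list[tuple[float, float]] | tuple[float, float],
    histogram: np.ndarray | None = None,
) -> Trajectory:
    """Trajectory from explicit frames and points (or one constant point)."""
    t = Trajectory(camera_id=camera_id, local_id=local_id)
    if isinstance(xy, tuple):
        xy = [xy] * len(frames)
    for f, (x, y) in zip(frames, xy):
        t.add(f, GroundPoint(float(x), float(y)))
    t.mean_histogram = histogram
    return t


def peaked_histogram(peak: int, n: int = 48, minor: float = 0.1) -> np.ndarray:
    """A normalized histogram with most mass in one bin — a stand-in for a
    uniform-color appearance."""
    h = np.full(n, minor / (n - 1))
    h[peak] = 1.0 - minor
    return h / h.sum()


@pytest.fixture(scope="session")
def clean_scene():
    """One noiseless fast scene plus its pipeline result, shared across
    tests (deterministic, so session scope is safe)."""
    from ortrack import PipelineConfig, get_preset, run_pipeline, simulate_scene

    cfg = get_preset("clean_fast", seed=1)
    scene, files = simulate_scene(cfg)
    gt = {c: scene.gt_frame_index(c) for c in cfg.camera_ids}
    result = run_pipeline(files, scene.homographies, PipelineConfig(),
                          gt_by_camera=gt, n_frames=cfg.n_frames)
    return cfg, scene, files, gt, result
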