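"""Per-camera pose-detection streams and the confidence filter.

Detections follow the layout of common top-down pose estimators: 17 COCO
keypoints with per-keypoint confidences, a whole-pose confidence score
(which may exceed 1), a bounding box and an optional appearance histogram.
A detection survives filtering only if its pose score is at least T11 and
at least one ankle confidence is at least T12 — low-confidence poses and
poses whose feet were not seen cannot be localized on the ground plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

N_KEYPOINTS = 17
# COCO keypoint order: ankles are the last two entries.
LEFT_ANKLE = 15
RIGHT_ANKLE = 16


class DetectionSchemaError(ValueError):
    """A detection record violates the documented schema."""


@dataclass
class Detection:
    """One person in one frame of one camera."""

    camera_id: str
    frame: int
    keypoints: np.ndarray          # (17, 2) pixel coordinates
    keypoint_scores: np.ndarray    # (17,) confidences >= 0
    pose_score: float              # whole-pose confidence, unbounded above
    bbox: tuple[float, float, float, float]  # x_min, y_min, width, height
    bbox_score: float = 1.0
    histogram: Optional[np.ndarray] = None   # appearance histogram, L1-normalized

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        self.keypoint_scores = np.asarray(self.keypoint_scores, dtype=float)
        if self.keypoints.shape != (N_KEYPOINTS, 2):
            raise DetectionSchemaError(
                f"expected {N_KEYPOINTS} keypoints, got shape {self.keypoints.shape}")
        if self.keypoint_scores.shape != (N_KEYPOINTS,):
            raise DetectionSchemaError(
                f"expected {N_KEYPOINTS} keypoint scores, got shape {self.keypoint_scores.shape}")
        if self.frame < 0:
            raise DetectionSchemaError(f"frame must be >= 0, got {self.frame}")
        if len(self.bbox) != 4 or self.bbox[2] <= 0 or self.bbox[3] <= 0:
            raise DetectionSchemaError(f"bbox must have positive width/height, got {self.bbox}")
        if self.histogram is not None:
            self.histogram = np.asarray(self.histogram, dtype=float)

    @property
    def left_ankle(self) -> tuple[float, float]:
        return tuple(self.keypoints[LEFT_ANKLE])

    @property
    def right_ankle(self) -> tuple[float, float]:
        return tuple(self.keypoints[RIGHT_ANKLE])

    @property
    def left_ankle_score(self) -> float:
        return float(self.keypoint_scores[LEFT_ANKLE])

    @property
    def right_ankle_score(self) -> float:
        return float(self.keypoint_scores[RIGHT_ANKLE])


@dataclass(frozen=True)
class FilterConfig:
    """Confidence thresholds for screening detections.

    T11: minimum whole-pose confidence (default 2, on the unbounded
         pose-score scale of top-down estimators).
    T12: minimum ankle confidence; at least one of the two ankles must
         reach it (default 0.6).
    """

    T11: float = 2.0
    T12: float = 0.6

    def __post_init__(self) -> None:
        if self.T11 < 0 or self.T12 < 0:
            raise ValueError("confidence thresholds must be >= 0")


@dataclass
class DetectionFile:
    """All detections of one camera, sorted by frame."""

    camera_id: str
    fps: float = 60.0
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.detections.sort(key=lambda d: d.frame)

    def by_frame(self) -> dict[int, list[Detection]]:
        out: dict[int, list[Detection]] = {}
        for d in self.detections:
            out.setdefault(d.frame, []).append(d)
        return out


def keep_detection(det: Detection, cfg: FilterConfig) -> bool:
    """The screening rule: drop a pose whose whole-pose score is below T11,
    or whose two ankle confidences are both below T12 (strict comparisons,
    so scores equal to a threshold survive)."""
    if det.pose_score < cfg.T11:
        return False
    return det.left_ankle_score >= cfg.T12 or det.right_ankle_score >= cfg.T12


def filter_detections(dets: Iterable[Detection], cfg: FilterConfig) -> list[Detection]:
    """Apply the confidence filter, preserving order."""
    return [d for d in dets if keep_detection(d, cfg)]


def filter_detection_file(df: DetectionFile, cfg: FilterConfig) -> DetectionFile:
    return DetectionFile(camera_id=df.camera_id, fps=df.fps,
                         detections=filter_detections(df.detections, cfg))


# ---------------------------------------------------------------------------
# JSON serialization.  One file per camera:
# {"camera_id": ..., "fps": 60, "detections": [
#     {"frame": int, "keypoints": [[x, y, score] x 17], "pose_score": float,
#      "bbox": [x, y, w, h], "bbox_score": float, "histogram": [...]?}, ...]}
# The keypoint triplet layout mirrors common pose-estimator JSON output so
# real detector results can be converted by a thin adapter.

def _det_to_record(d: Detection) -> dict:
    rec = {
        "frame": int(d.frame),
        "keypoints": [[float(x), float(y), float(s)]
                      for (x, y), s in zip(d.keypoints, d.keypoint_scores)],
        "pose_score": float(d.pose_score),
        "bbox": [float(v) for v in d.bbox],
        "bbox_score": float(d.bbox_score),
    }
    if d.histogram is not None:
        rec["histogram"] = [float(v) for v in d.histogram]
    return rec


def _record_to_det(rec: dict, camera_id: str, index: int) -> Detection:
    try:
        kps = rec["keypoints"]
        if not isinstance(kps, list) or any(len(k) != 3 for k in kps):
            raise DetectionSchemaError(
                f"record {index}: keypoints must be [x, y, score] triplets")
        arr = np.asarray(kps, dtype=float)
        return Detection(
            camera_id=camera_id,
            frame=int(rec["frame"]),
            keypoints=arr[:, :2],
            keypoint_scores=arr[:, 2],
            pose_score=float(rec["pose_score"]),
            bbox=tuple(float(v) for v in rec["bbox"]),
            bbox_score=float(rec.get("bbox_score", 1.0)),
            histogram=rec.get("histogram"),
        )
    except KeyError as exc:
        raise DetectionSchemaError(f"record {index}: missing required field {exc}") from exc
    except (TypeError, ValueError) as exc:
        if isinstance(exc, DetectionSchemaError):
            raise
        raise DetectionSchemaError(f"record {index}: malformed record ({exc})") from exc


def write_detections(df: DetectionFile, path: str | Path) -> None:
    data = {
        "camera_id": df.camera_id,
        "fps": df.fps,
        "detections": [_det_to_record(d) for d in df.detections],
    }
    Path(path).write_text(json.dumps(data))


def read_detections(path: str | Path) -> DetectionFile:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise DetectionSchemaError(f"{path}: not valid JSON ({exc})") from exc
    try:
        camera_id = str(data["camera_id"])
        dets = data["detections"]
    except (KeyError, TypeError) as exc:
        raise DetectionSchemaError(f"{path}: missing top-level field {exc}") from exc
    return DetectionFile(
        camera_id=camera_id,
        fps=float(data.get("fps", 60.0)),
        detections=[_record_to_det(rec, camera_id, i) for i, rec in enumerate(dets)],
    )
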