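"""End-to-end orchestration: filter -> localize -> link per camera, then
cluster + noise reassignment globally, then (optionally) evaluate.

Every stage logs its in/out counts so the confidence-filtering trade-off
(good detections lost vs. bad detections removed) stays observable, and
the whole run is deterministic given the inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .detection_io import DetectionFile, FilterConfig, filter_detections
from .geometry import Homography
from .metrics import evaluate_tracking
from .reid import IdentityClustering, ReidConfig, reidentify
from .tracking import (TrackerConfig, Trajectory, link_tracks,
                       localize_detections, trajectories_to_frame_table)

log = logging.getLogger("ortrack")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters in one place; the defaults are the framework's
    reference operating point (T11=2, T12=0.6, T13=40 cm, T14=60 frames,
    T22=120 cm, T23=0.6, and a core threshold of half the sequence length
    — 7200 frames for a 4-minute 60 FPS video)."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    t21: Optional[int] = None       # None: half the sequence length
    t22: float = 120.0
    t23: float = 0.6
    o_min: int = 30
    overlap_tolerance: int = 0
    match_threshold_cm: float = 100.0
    gt_stride: int = 1              # evaluate every Nth frame only

    def reid_config(self, n_frames: int) -> ReidConfig:
        t21 = self.t21 if self.t21 is not None else max(1, n_frames // 2)
        return ReidConfig(T21=t21, T22=self.t22, T23=self.t23,
                          O_min=self.o_min,
                          overlap_tolerance=self.overlap_tolerance)


@dataclass
class PipelineResult:
    trajectories: dict[str, list[Trajectory]]
    clustering: IdentityClustering
    global_ids: dict[tuple[str, int], int]
    stage_counts: dict
    report: Optional[dict] = None

    def labeled_table(self) -> pd.DataFrame:
        all_trajs = [t for ts in self.trajectories.values() for t in ts]
        return trajectories_to_frame_table(all_trajs, self.global_ids)

    def predictions_by_camera(self) -> dict[str, dict]:
        """Predictions in the evaluator's frame-indexed layout, labeled by
        global id."""
        out: dict[str, dict[int, list[tuple[int, float, float]]]] = {}
        for cam, trajs in self.trajectories.items():
            idx: dict[int, list[tuple[int, float, float]]] = {}
            for t in trajs:
                gid = self.global_ids[(t.camera_id, t.local_id)]
                for f, p in t.points.items():
                    idx.setdefault(f, []).append((gid, p.X, p.Y))
            out[cam] = {f: sorted(v) for f, v in idx.items()}
        return out


def run_pipeline(
    detections: Mapping[str, DetectionFile],
    homographies: Mapping[str, Homography],
    cfg: PipelineConfig = PipelineConfig(),
    gt_by_camera: Optional[Mapping[str, Mapping]] = None,
    n_frames: Optional[int] = None,
) -> PipelineResult:
    """Run the full tracking + ReID chain.

    `detections` maps camera_id to its detection file; every camera must
    have a homography.  If ground truth is supplied the evaluation report
    (per-camera MOTA/IDF1, global NMI) is attached to the result.
    `n_frames` sets the sequence length used for the default core
    threshold; inferred from the data when omitted.
    """
    missing = sorted(set(detections) - set(homographies))
    if missing:
        raise ConfigurationError(
            f"no homography for camera(s): {', '.join(missing)}")

    counts: dict = {"cameras": {}}
    per_camera: dict[str, list[Trajectory]] = {}
    max_frame = 0
    for cam in sorted(detections):
        df = detections[cam]
        t0 = time.perf_counter()
        kept = filter_detections(df.detections, cfg.filter)
        localized = localize_detections(kept, homographies[cam])
        trajs = link_tracks(localized, cfg.tracker, camera_id=cam)
        per_camera[cam] = trajs
        if df.detections:
            max_frame = max(max_frame, max(d.frame for d in df.detections))
        counts["cameras"][cam] = {
            "detections_in": len(df.detections),
            "kept_after_filter": len(kept),
            "filtered_out": len(df.detections) - len(kept),
            "trajectories": len(trajs),
            "linked_points": sum(t.observed_length for t in trajs),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        log.info("%s: %d detections -> %d kept -> %d tracklets",
                 cam, len(df.detections), len(kept), len(trajs))

    seq_len = n_frames if n_frames is not None else max_frame + 1
    reid_cfg = cfg.reid_config(seq_len)
    t0 = time.perf_counter()
    all_trajs = [t for cam in sorted(per_camera) for t in per_camera[cam]]
    clustering, gids = reidentify(all_trajs, reid_cfg)
    counts["reid"] = {
        "trajectories": len(all_trajs),
        "clusters": len(clustering.clusters),
        "T21": reid_cfg.T21,
        "seconds": round(time.perf_counter() - t0, 3),
    }
    log.info("reid: %d tracklets -> %d identities", len(all_trajs),
             len(clustering.clusters))

    result = PipelineResult(trajectories=per_camera, clustering=clustering,
                            global_ids=gids, stage_counts=counts)
    if gt_by_camera is not None:
        result.report = evaluate_tracking(
            gt_by_camera, result.predictions_by_camera(),
            match_threshold_cm=cfg.match_threshold_cm)
    return result


def parameter_sweep(
    detections: Mapping[str, DetectionFile],
    homographies: Mapping[str, Homography],
    gt_by_camera: Mapping[str, Mapping],
    cfg: PipelineConfig = PipelineConfig(),
    t22_values: Sequence[float] = (40.0, 80.0, 120.0, 160.0, 200.0),
    t23_values: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
    n_frames: Optional[int] = None,
) -> pd.DataFrame:
    """NMI over a (T22, T23) grid on one scene, as a table with T22 rows
    and T23 columns.

    Filtering, localization and monocular linking do not depend on the
    ReID gates, so they run once and only the clustering stage is redone
    per cell; cells are independent of each other.
    """
    base = run_pipeline(detections, homographies, cfg, n_frames=n_frames)
    all_trajs = [t for cam in sorted(base.trajectories)
                 for t in base.trajectories[cam]]
    seq_len = n_frames if n_frames is not None else (
        1 + max((t.last_frame for t in all_trajs), default=0))

    table = np.zeros((len(t22_values), len(t23_values)))
    for i, t22 in enumerate(t22_values):
        for j, t23 in enumerate(t23_values):
            cell_cfg = dataclasses.replace(cfg, t22=t22, t23=t23)
            clustering, gids = reidentify(all_trajs, cell_cfg.reid_config(seq_len))
            cell = PipelineResult(trajectories=base.trajectories,
                                  clustering=clustering, global_ids=gids,
                                  stage_counts={})
            report = evaluate_tracking(gt_by_camera, cell.predictions_by_camera(),
                                       match_threshold_cm=cfg.match_threshold_cm)
            table[i, j] = report["nmi"] if report["nmi"] is not None else np.nan
    return pd.DataFrame(table, index=pd.Index(t22_values, name="T22_cm"),
                        columns=pd.Index(t23_values, name="T23"))


def write_report(result: PipelineResult, path: str | Path) -> None:
    payload = {"stage_counts": result.stage_counts}
    if result.report is not None:
        payload["evaluation"] = result.report
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
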