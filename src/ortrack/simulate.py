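"""Seeded synthetic multi-camera room scenes.

The generator emulates the recording setup the tracking framework is
designed for: a narrow room (default 600 x 900 cm) observed by four
synchronized oblique cameras at 60 FPS, several staff members in a small
number of uniform colors (so appearance is confusable), waypoint-and-
dwell motion, detector noise (ankle jitter, missed detections, low-score
false positives) and per-camera occlusion zones that break tracklets for
some cameras while others keep full coverage.

Everything is reproducible from the seed: cameras, motion, visibility
and noise draws are all derived from independent child generators of one
seed sequence, so the emitted detection files are identical across runs.

What the simulator does NOT model: articulated body motion (keypoints
other than the ankles are a schematic skeleton), photometric effects,
camera desynchronization, and detector confusion between nearby people.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detection_io import Detection, DetectionFile, N_KEYPOINTS, write_detections
from .geometry import GroundPoint, Homography, write_homographies

IMG_W, IMG_H = 1920, 1080
PERSON_HEIGHT_CM = 175.0
ANKLE_HALF_GAP_PX = 8.0


@dataclass(frozen=True)
class OcclusionZone:
    """A ground rectangle inside which one camera loses detections."""

    camera_index: int
    x0: float
    y0: float
    x1: float
    y1: float
    drop_prob: float = 0.95

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)


@dataclass(frozen=True)
class SimConfig:
    """Scene parameters.  Defaults mirror a 4-minute, 4-camera 60 FPS
    recording of a 6 x 9 m room with six staff members in three uniform
    colors; rates are per frame."""

    room_width: float = 600.0      # cm, X extent
    room_depth: float = 900.0      # cm, Y extent
    n_identities: int = 6
    n_uniform_classes: int = 3
    n_cameras: int = 4
    n_frames: int = 14_400
    fps: float = 60.0
    walk_speed_mean: float = 40.0  # cm/s
    walk_speed_sd: float = 10.0
    min_separation: float = 40.0   # personal space between two people, cm
    station_spread: Optional[float] = None  # confine stations near room center
    dwell_mean_s: float = 6.0      # pause at each station point
    dwell_sd_s: float = 3.0
    ankle_noise_px: float = 2.0
    miss_rate: float = 0.02        # detector misses outside occlusion
    fp_rate: float = 0.005         # false positives per camera per frame
    occlusion_zones: tuple[OcclusionZone, ...] = ()
    hist_bins: int = 48            # 3 channels x 16 bins, concatenated
    hist_jitter: float = 0.02      # within-class per-detection jitter (sd)
    pose_score_mean: float = 3.0   # kept detections; threshold T11 = 2
    pose_score_sd: float = 0.3
    ankle_score_mean: float = 0.85
    ankle_score_sd: float = 0.08
    fp_pose_score_mean: float = 1.2   # false positives sit mostly below T11
    fp_pose_score_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.room_width <= 0 or self.room_depth <= 0:
            raise ValueError("room dimensions must be positive")
        for r in (self.miss_rate, self.fp_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")

    @property
    def camera_ids(self) -> list[str]:
        return [f"cam{i}" for i in range(self.n_cameras)]


@dataclass
class GroundTruthScene:
    """The simulated truth: per-identity ground tracks, per-camera
    homographies and per-camera visibility (geometric visibility minus
    occlusion — what an annotator watching that camera could label)."""

    config: SimConfig
    positions: np.ndarray                       # (n_identities, n_frames, 2) cm
    homographies: dict[str, Homography]         # image -> ground
    ground_to_image: dict[str, Homography]
    visibility: dict[str, np.ndarray]           # camera -> (n_identities, n_frames) bool
    uniform_class: list[int]
    class_histograms: np.ndarray                # (n_classes, hist_bins)

    def gt_frame_index(self, camera_id: str, stride: int = 1) -> dict:
        """Ground truth in the evaluator's frame-indexed layout, optionally
        subsampled (stride 60 emulates one annotation per second)."""
        vis = self.visibility[camera_id]
        out: dict[int, list[tuple[int, float, float]]] = {}
        for f in range(0, self.config.n_frames, stride):
            entries = [(i, float(self.positions[i, f, 0]), float(self.positions[i, f, 1]))
                       for i in range(self.config.n_identities) if vis[i, f]]
            if entries:
                out[f] = entries
        return out


# ---------------------------------------------------------------------------
# Cameras

def _pinhole_ground_homography(
    position: np.ndarray, target: np.ndarray, focal: float
) -> np.ndarray:
    """Ground(Z=0) -> image homography of a pinhole camera at `position`
    looking at `target` (world Z up): H = K [r1 r2 t]."""
    fwd = target - position
    fwd = fwd / np.linalg.norm(fwd)
    up = np.array([0.0, 0.0, 1.0])
    right = np.cross(fwd, up)
    right /= np.linalg.norm(right)
    down = np.cross(fwd, right)
    R = np.stack([right, down, fwd])        # world -> camera
    t = -R @ position
    K = np.array([[focal, 0.0, IMG_W / 2.0],
                  [0.0, focal, IMG_H / 2.0],
                  [0.0, 0.0, 1.0]])
    return K @ np.column_stack([R[:, 0], R[:, 1], t])


def make_camera(
    index: int, room: tuple[float, float], rng: np.random.Generator,
    margin_px: float = 30.0, max_tries: int = 100,
) -> tuple[Homography, tuple[int, int]]:
    """Synthesize one oblique view of the room and return its exact
    image-to-ground homography plus the image bounds.

    The camera sits outside one side of the room (cycling through the four
    sides with the index), elevated, looking at the room center.  The
    focal length is chosen so that the whole room fits in frame, which
    guarantees full geometric visibility of every ground point; a draw
    whose geometry is degenerate (focal out of range, ill-conditioned
    homography) is rejected and redrawn.
    """
    W, D = room
    corners = np.array([[0.0, 0.0, 0.0], [W, 0.0, 0.0], [0.0, D, 0.0], [W, D, 0.0]])
    target = np.array([W / 2.0, D / 2.0, 0.0])
    side = index % 4
    for _ in range(max_tries):
        back = rng.uniform(150.0, 400.0)
        along = rng.uniform(0.3, 0.7)
        height = rng.uniform(220.0, 300.0)
        if side == 0:
            pos = np.array([along * W, -back, height])
        elif side == 1:
            pos = np.array([W + back, along * D, height])
        elif side == 2:
            pos = np.array([along * W, D + back, height])
        else:
            pos = np.array([-back, along * D, height])
        H1 = _pinhole_ground_homography(pos, target, focal=1.0)
        hc = np.column_stack([corners[:, 0], corners[:, 1], np.ones(4)]) @ H1.T
        if np.any(hc[:, 2] <= 1e-6):      # a corner behind the camera
            continue
        xn = hc[:, 0] / hc[:, 2] - IMG_W / 2.0
        yn = hc[:, 1] / hc[:, 2] - IMG_H / 2.0
        # largest focal that keeps all corners margin_px inside the frame
        fx = np.inf if np.abs(xn).max() == 0 else (IMG_W / 2 - margin_px) / np.abs(xn).max()
        fy = np.inf if np.abs(yn).max() == 0 else (IMG_H / 2 - margin_px) / np.abs(yn).max()
        focal = 0.95 * min(fx, fy)
        if not 150.0 <= focal <= 4000.0:
            continue
        Hg2i = _pinhole_ground_homography(pos, target, focal=focal)
        if np.linalg.cond(Hg2i) > 1e7:
            continue
        cam_id = f"cam{index}"
        g2i = Homography(Hg2i, camera_id=cam_id)
        return g2i.inverse(), (IMG_W, IMG_H)
    raise RuntimeError(f"could not draw a valid camera {index} in {max_tries} tries")


# ---------------------------------------------------------------------------
# Motion

def _simulate_motion(cfg: SimConfig, rng: np.random.Generator,
                     station_center: Optional[np.ndarray] = None,
                     station_spread: Optional[float] = None) -> np.ndarray:
    """Waypoint-and-dwell walks, one (n_frames, 2) track per identity.

    Identities walk in straight legs at a per-leg speed ~ N(mean, sd)
    (floored at 5 cm/s) toward random station points, then dwell there
    for ~ N(dwell_mean, dwell_sd) seconds.  Stations keep a 50 cm margin
    from the walls; `station_center`/`station_spread` confine them for
    crowded scenes.  People occupy space: after each step, pairs closer
    than `min_separation` (shoulder distance) are pushed apart
    symmetrically, so two bodies never coincide.
    """
    margin = 50.0
    lo = np.array([margin, margin])
    hi = np.array([cfg.room_width - margin, cfg.room_depth - margin])
    n = cfg.n_identities

    def draw_station() -> np.ndarray:
        if station_center is not None:
            p = station_center + rng.normal(0.0, station_spread, 2)
            return np.clip(p, lo, hi)
        return rng.uniform(lo, hi)

    def draw_speed() -> float:
        return max(rng.normal(cfg.walk_speed_mean, cfg.walk_speed_sd), 5.0) / cfg.fps

    def draw_dwell() -> int:
        return max(int(round(max(rng.normal(cfg.dwell_mean_s, cfg.dwell_sd_s), 0.5)
                             * cfg.fps)), 1)

    pos = np.array([draw_station() for _ in range(n)])
    target = np.array([draw_station() for _ in range(n)])
    step = np.array([draw_speed() for _ in range(n)])
    dwell = np.zeros(n, dtype=int)

    out = np.empty((n, cfg.n_frames, 2))
    out[:, 0] = pos
    for f in range(1, cfg.n_frames):
        for i in range(n):
            if dwell[i] > 0:
                dwell[i] -= 1
                if dwell[i] == 0:
                    target[i] = draw_station()
                    step[i] = draw_speed()
                continue
            delta = target[i] - pos[i]
            dist = float(np.hypot(delta[0], delta[1]))
            if dist <= step[i]:
                pos[i] = target[i]
                dwell[i] = draw_dwell()
            else:
                pos[i] = pos[i] + delta / dist * step[i]
        if cfg.min_separation > 0.0:
            for i in range(n):
                for j in range(i + 1, n):
                    dvec = pos[j] - pos[i]
                    d = float(np.hypot(dvec[0], dvec[1]))
                    if d >= cfg.min_separation:
                        continue
                    if d < 1e-9:
                        ang = rng.uniform(0.0, 2.0 * np.pi)
                        dvec = np.array([np.cos(ang), np.sin(ang)])
                        d = 1.0
                    push = (cfg.min_separation - d) / 2.0
                    dirv = dvec / d
                    pos[i] = pos[i] - dirv * push
                    pos[j] = pos[j] + dirv * push
            np.clip(pos, lo, hi, out=pos)
        out[:, f] = pos
    return out


# ---------------------------------------------------------------------------
# Appearance

def _uniform_class_histograms(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """One well-separated base histogram per uniform class: each class
    concentrates its mass on a few distinct bins per channel."""
    bins_per_channel = cfg.hist_bins // 3
    out = np.zeros((cfg.n_uniform_classes, cfg.hist_bins))
    for c in range(cfg.n_uniform_classes):
        for ch in range(3):
            peak = (c * bins_per_channel) // max(cfg.n_uniform_classes, 1)
            peak = (peak + rng.integers(0, 2)) % bins_per_channel
            lo = ch * bins_per_channel
            out[c, lo + peak] = 0.7
            out[c, lo + (peak + 1) % bins_per_channel] = 0.2
            out[c, lo + (peak + 2) % bins_per_channel] = 0.1
    return out / out.sum(axis=1, keepdims=True)


def _jitter_histogram(base: np.ndarray, rng: np.random.Generator, sd: float) -> np.ndarray:
    h = np.clip(base + rng.normal(0.0, sd, base.shape), 0.0, None)
    s = h.sum()
    return h / s if s > 0 else np.full_like(base, 1.0 / len(base))


# ---------------------------------------------------------------------------
# Detection synthesis

def _skeleton(foot_xy: np.ndarray, height_px: float,
              rng: np.random.Generator, noise_px: float) -> np.ndarray:
    """Schematic 17-keypoint pose above an image-space foot point.  Only
    the ankles (indices 15, 16) matter downstream; their midpoint equals
    the projected foot location up to the added noise."""
    x, y = foot_xy
    kp = np.empty((N_KEYPOINTS, 2))
    # head + face (0-4), shoulders (5-6), elbows (7-8), wrists (9-10),
    # hips (11-12), knees (13-14): fractions of body height above the feet
    frac = [1.0, 1.02, 1.02, 1.0, 1.0, 0.85, 0.85, 0.65, 0.65,
            0.45, 0.45, 0.52, 0.52, 0.27, 0.27]
    lateral = [0.0, -0.03, 0.03, -0.06, 0.06, -0.12, 0.12, -0.16, 0.16,
               -0.17, 0.17, -0.08, 0.08, -0.08, 0.08]
    for k in range(15):
        kp[k] = (x + lateral[k] * height_px, y - frac[k] * height_px)
    kp[15] = (x - ANKLE_HALF_GAP_PX, y)
    kp[16] = (x + ANKLE_HALF_GAP_PX, y)
    if noise_px > 0:
        kp += rng.normal(0.0, noise_px, kp.shape)
    return kp


def simulate_scene(cfg: SimConfig) -> tuple[GroundTruthScene, dict[str, DetectionFile]]:
    """Generate a scene and its per-camera detection files.

    Visibility in a camera requires the projected foot point inside the
    frame and survival of that camera's occlusion draw; a visible identity
    then emits a detection unless the detector miss draw removes it.
    False positives are injected at uniform image positions with low pose
    scores (mostly removed by the default confidence filter).
    """
    root = np.random.SeedSequence(cfg.seed)
    cam_ss, motion_ss, appear_ss, *noise_ss = root.spawn(3 + cfg.n_cameras)

    cam_rng = np.random.default_rng(cam_ss)
    homographies: dict[str, Homography] = {}
    ground_to_image: dict[str, Homography] = {}
    for i in range(cfg.n_cameras):
        h, _bounds = make_camera(i, (cfg.room_width, cfg.room_depth), cam_rng)
        homographies[h.camera_id] = h
        ground_to_image[h.camera_id] = h.inverse()

    center = (np.array([cfg.room_width / 2.0, cfg.room_depth / 2.0])
              if cfg.station_spread is not None else None)
    positions = _simulate_motion(cfg, np.random.default_rng(motion_ss),
                                 station_center=center,
                                 station_spread=cfg.station_spread)

    appear_rng = np.random.default_rng(appear_ss)
    class_hists = _uniform_class_histograms(cfg, appear_rng)
    uniform_class = [i % cfg.n_uniform_classes for i in range(cfg.n_identities)]

    visibility: dict[str, np.ndarray] = {}
    files: dict[str, DetectionFile] = {}
    n_id, n_frames = cfg.n_identities, cfg.n_frames
    flat = positions.reshape(-1, 2)

    for ci, cam_id in enumerate(cfg.camera_ids):
        rng = np.random.default_rng(noise_ss[ci])
        g2i = ground_to_image[cam_id]
        v = np.column_stack([flat, np.ones(len(flat))]) @ g2i.matrix.T
        w = v[:, 2]
        img = (v[:, :2] / w[:, None]).reshape(n_id, n_frames, 2)
        depth_ok = (w > 1e-9).reshape(n_id, n_frames)
        in_frame = ((img[..., 0] >= 0) & (img[..., 0] < IMG_W)
                    & (img[..., 1] >= 0) & (img[..., 1] < IMG_H) & depth_ok)

        occluded = np.zeros((n_id, n_frames), dtype=bool)
        for zone in cfg.occlusion_zones:
            if zone.camera_index != ci:
                continue
            inside = zone.contains(positions[..., 0], positions[..., 1])
            draws = rng.random((n_id, n_frames)) < zone.drop_prob
            occluded |= inside & draws
        vis = in_frame & ~occluded
        visibility[cam_id] = vis

        missed = rng.random((n_id, n_frames)) < cfg.miss_rate
        emit = vis & ~missed

        dets: list[Detection] = []
        for f in range(n_frames):
            for i in range(n_id):
                if not emit[i, f]:
                    continue
                foot = img[i, f]
                height_px = _apparent_height_px(g2i, positions[i, f], foot)
                kp = _skeleton(foot, height_px, rng, cfg.ankle_noise_px)
                scores = np.clip(rng.normal(0.8, 0.05, N_KEYPOINTS), 0.0, 1.0)
                scores[15] = max(rng.normal(cfg.ankle_score_mean, cfg.ankle_score_sd), 0.0)
                scores[16] = max(rng.normal(cfg.ankle_score_mean, cfg.ankle_score_sd), 0.0)
                bbox_w = max(height_px * 0.35, 4.0)
                bbox = (foot[0] - bbox_w / 2, foot[1] - height_px, bbox_w,
                        max(height_px, 4.0) * 1.02)
                dets.append(Detection(
                    camera_id=cam_id, frame=f, keypoints=kp,
                    keypoint_scores=scores,
                    pose_score=max(rng.normal(cfg.pose_score_mean, cfg.pose_score_sd), 0.0),
                    bbox=bbox, bbox_score=float(np.clip(rng.normal(0.9, 0.05), 0.0, 1.0)),
                    histogram=_jitter_histogram(class_hists[uniform_class[i]],
                                                rng, cfg.hist_jitter),
                ))
            if cfg.fp_rate > 0 and rng.random() < cfg.fp_rate:
                x = rng.uniform(50, IMG_W - 50)
                y = rng.uniform(IMG_H * 0.4, IMG_H - 10)
                kp = _skeleton(np.array([x, y]), rng.uniform(80, 250), rng, 5.0)
                dets.append(Detection(
                    camera_id=cam_id, frame=f, keypoints=kp,
                    keypoint_scores=np.clip(rng.normal(0.4, 0.2, N_KEYPOINTS), 0.0, 1.0),
                    pose_score=max(rng.normal(cfg.fp_pose_score_mean,
                                              cfg.fp_pose_score_sd), 0.0),
                    bbox=(x - 30, y - 150, 60, 155), bbox_score=0.5,
                    histogram=_jitter_histogram(
                        np.full(cfg.hist_bins, 1.0 / cfg.hist_bins), rng, 0.05),
                ))
        files[cam_id] = DetectionFile(camera_id=cam_id, fps=cfg.fps, detections=dets)

    scene = GroundTruthScene(
        config=cfg, positions=positions, homographies=homographies,
        ground_to_image=ground_to_image, visibility=visibility,
        uniform_class=uniform_class, class_histograms=class_hists,
    )
    return scene, files


def _apparent_height_px(g2i: Homography, ground_xy: np.ndarray,
                        foot_img: np.ndarray) -> float:
    """Rough pixel height of a person at a ground point: scale of the
    homography's local Jacobian converts cm to px at that location."""
    eps = 1.0
    p0 = np.array([ground_xy[0], ground_xy[1], 1.0]) @ g2i.matrix.T
    p1 = np.array([ground_xy[0] + eps, ground_xy[1], 1.0]) @ g2i.matrix.T
    p2 = np.array([ground_xy[0], ground_xy[1] + eps, 1.0]) @ g2i.matrix.T
    a = p0[:2] / p0[2]
    scale = 0.5 * (np.linalg.norm(p1[:2] / p1[2] - a)
                   + np.linalg.norm(p2[:2] / p2[2] - a))
    return float(np.clip(PERSON_HEIGHT_CM * scale, 40.0, IMG_H * 0.9))


# ---------------------------------------------------------------------------
# Presets

def scenario_presets(fast: bool = False) -> dict[str, SimConfig]:
    """Named scene configurations.

    "clean": no noise or occlusion — the pipeline should be exact.
    "broken_tracklets": every camera except cam0 has a large occlusion
        zone, so cam0 keeps core-length trajectories while the others
        fragment with gaps far longer than the tracker memory.
    "confusable_uniforms": all identities share one histogram class.
    "crowded": station points confined within ~50 cm of the room center.

    `fast` variants shrink the scene to 1,800 frames (30 s) for quick runs.
    """
    n_frames = 1_800 if fast else 14_400
    base = dict(n_frames=n_frames)
    presets: dict[str, SimConfig] = {}
    presets["clean"] = SimConfig(
        n_identities=4, ankle_noise_px=0.0, miss_rate=0.0, fp_rate=0.0,
        hist_jitter=0.0, n_uniform_classes=4,
        pose_score_sd=0.0, ankle_score_sd=0.0, **base)
    zones = tuple(
        OcclusionZone(camera_index=ci, x0=100.0, y0=250.0, x1=500.0, y1=650.0,
                      drop_prob=1.0)
        for ci in (1, 2, 3))
    presets["broken_tracklets"] = SimConfig(
        n_identities=4, n_uniform_classes=2, occlusion_zones=zones, **base)
    presets["confusable_uniforms"] = SimConfig(
        n_identities=5, n_uniform_classes=1, **base)
    presets["crowded"] = SimConfig(
        n_identities=6, n_uniform_classes=3, station_spread=50.0, **base)
    return presets


def get_preset(name: str, seed: int = 0) -> SimConfig:
    """Look up a preset by name; a "_fast" suffix selects the short variant."""
    fast = name.endswith("_fast")
    base = name[:-5] if fast else name
    presets = scenario_presets(fast=fast)
    if base not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from "
                       f"{sorted(presets)} (optionally with '_fast')")
    return dataclasses.replace(presets[base], seed=seed)


# ---------------------------------------------------------------------------
# On-disk emission

def write_scene(scene: GroundTruthScene, files: dict[str, DetectionFile],
                outdir: str | Path) -> dict[str, Path]:
    """Emit detection JSON per camera, the homography map, ground-truth CSV
    (trajectory schema with global ids) and a manifest of the draw."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cam_id, df in files.items():
        p = outdir / f"detections_{cam_id}.json"
        write_detections(df, p)
        paths[f"detections_{cam_id}"] = p
    hp = outdir / "homographies.json"
    write_homographies(scene.homographies.values(), hp)
    paths["homographies"] = hp

    rows = []
    cfg = scene.config
    for cam_id in cfg.camera_ids:
        vis = scene.visibility[cam_id]
        for i in range(cfg.n_identities):
            for f in np.nonzero(vis[i])[0]:
                rows.append((cam_id, i, i, int(f),
                             scene.positions[i, f, 0], scene.positions[i, f, 1]))
    gt = pd.DataFrame(rows, columns=["camera_id", "local_id", "global_id",
                                     "frame", "X_cm", "Y_cm"])
    gp = outdir / "ground_truth.csv"
    gt.to_csv(gp, index=False, float_format="%.6f")
    paths["ground_truth"] = gp

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) and k == "occlusion_zones"
                       else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "uniform_class": scene.uniform_class,
        "cameras": cfg.camera_ids,
    }
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=1, default=str))
    paths["manifest"] = mp
    return paths
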