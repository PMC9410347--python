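"""Ground-plane geometry: homographies and image-space foot localization.

A person's position in a camera image is summarized by the midpoint of
their two ankle keypoints; that image point is mapped onto a shared world
ground plane (units: cm) by a per-camera 3x3 homography.  Homographies are
stored normalized so that the bottom-right entry equals 1, which makes
equality comparisons well defined (a projective transform is only unique
up to scale).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class GeometryError(ValueError):
    """Invalid geometric input (non-finite point, degenerate homography...)."""


class PointAtInfinityError(GeometryError):
    """Homogeneous division by a (near-)zero third coordinate."""


@dataclass(frozen=True)
class ImagePoint:
    """Pixel coordinates; origin top-left, x rightward, y downward."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"image point must be finite, got ({self.x}, {self.y})")


@dataclass(frozen=True)
class GroundPoint:
    """World ground-plane coordinates in cm."""

    X: float
    Y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.X) and math.isfinite(self.Y)):
            raise GeometryError(f"ground point must be finite, got ({self.X}, {self.Y})")

    def distance_to(self, other: "GroundPoint") -> float:
        return math.hypot(self.X - other.X, self.Y - other.Y)


_DET_TOL = 1e-12


@dataclass
class Homography:
    """3x3 projective map from a camera's image plane to the ground plane.

    The matrix is normalized on construction so its bottom-right entry is 1
    (when nonzero) and is required to be invertible.
    """

    matrix: np.ndarray
    camera_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise GeometryError(f"homography must be 3x3, got shape {m.shape}")
        if not np.all(np.isfinite(m)):
            raise GeometryError("homography entries must be finite")
        if abs(m[2, 2]) > _DET_TOL:
            m = m / m[2, 2]
        if abs(np.linalg.det(m)) <= _DET_TOL:
            raise GeometryError("homography is singular (|det| <= 1e-12)")
        self.matrix = m

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix), camera_id=self.camera_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Homography):
            return NotImplemented
        return np.allclose(self.matrix, other.matrix) and self.camera_id == other.camera_id


def foot_location(left_ankle: ImagePoint, right_ankle: ImagePoint) -> ImagePoint:
    """Midpoint of the two ankle keypoints — the image-space foot position."""
    return ImagePoint((left_ankle.x + right_ankle.x) / 2.0,
                      (left_ankle.y + right_ankle.y) / 2.0)


def apply_homography(H: Homography, p: ImagePoint) -> GroundPoint:
    """Map an image point onto the ground plane.

    The homogeneous scale is eliminated by dividing through the third
    coordinate w; |w| <= 1e-12 indicates a point at infinity and raises.
    """
    v = H.matrix @ np.array([p.x, p.y, 1.0])
    w = v[2]
    if abs(w) <= _DET_TOL:
        raise PointAtInfinityError(
            f"point ({p.x}, {p.y}) maps to infinity under homography (w={w})")
    return GroundPoint(v[0] / w, v[1] / w)


def apply_homography_array(H: Homography, xy: np.ndarray) -> np.ndarray:
    """Vectorized homography application for an (n, 2) array of image points."""
    xy = np.asarray(xy, dtype=float)
    ones = np.ones((xy.shape[0], 1))
    v = np.hstack([xy, ones]) @ H.matrix.T
    w = v[:, 2]
    if np.any(np.abs(w) <= _DET_TOL):
        raise PointAtInfinityError("some points map to infinity under homography")
    return v[:, :2] / w[:, None]


def _hartley_normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity transform sending the centroid to the origin and the mean
    distance from it to sqrt(2)."""
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    s = math.sqrt(2.0) / d if d > 0 else 1.0
    T = np.array([[s, 0.0, -s * centroid[0]],
                  [0.0, s, -s * centroid[1]],
                  [0.0, 0.0, 1.0]])
    return T


def estimate_homography(
    correspondences: Sequence[tuple[ImagePoint, GroundPoint]],
    camera_id: str = "",
) -> tuple[Homography, float]:
    """Estimate an image-to-ground homography from point correspondences.

    Uses the normalized DLT: both point sets are Hartley-normalized, the
    homography is the null vector (smallest-singular-value right singular
    vector) of the 2n x 9 design matrix, and the normalizations are undone.
    With more than 4 correspondences this is the algebraic least-squares
    solution over all of them.

    Returns the homography and the RMS reprojection residual (cm).
    """
    if len(correspondences) < 4:
        raise GeometryError(
            f"homography estimation needs >= 4 correspondences, got {len(correspondences)}")
    src = np.array([[ip.x, ip.y] for ip, _ in correspondences], dtype=float)
    dst = np.array([[gp.X, gp.Y] for _, gp in correspondences], dtype=float)

    Ts = _hartley_normalization(src)
    Td = _hartley_normalization(dst)
    src_h = np.hstack([src, np.ones((len(src), 1))]) @ Ts.T
    dst_h = np.hstack([dst, np.ones((len(dst), 1))]) @ Td.T

    rows = []
    for (x, y, _), (X, Y, _) in zip(src_h, dst_h):
        rows.append([0, 0, 0, -x, -y, -1, Y * x, Y * y, Y])
        rows.append([x, y, 1, 0, 0, 0, -X * x, -X * y, -X])
    A = np.asarray(rows, dtype=float)
    _, s, vt = np.linalg.svd(A)
    if s[-2] <= 1e-9 * s[0]:
        raise GeometryError("degenerate correspondence configuration (rank-deficient DLT)")
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    try:
        hom = Homography(H, camera_id=camera_id)
    except GeometryError as exc:
        raise GeometryError(f"estimated homography is degenerate: {exc}") from exc

    mapped = apply_homography_array(hom, src)
    residual = float(np.sqrt(np.mean(np.sum((mapped - dst) ** 2, axis=1))))
    return hom, residual


# ---------------------------------------------------------------------------
# Homography file I/O: a single JSON map camera_id -> 3x3 row-major matrix.

def write_homographies(homographies: Iterable[Homography], path: str | Path) -> None:
    data = {h.camera_id: [[float(v) for v in row] for row in h.matrix]
            for h in homographies}
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


def read_homographies(path: str | Path) -> dict[str, Homography]:
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict):
        raise GeometryError(f"{path}: expected a JSON object camera_id -> matrix")
    return {cam: Homography(np.asarray(m, dtype=float), camera_id=cam)
            for cam, m in data.items()}
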