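"""Appearance histograms and the histogram correlation coefficient.

Surgical scrubs come in a handful of uniform colors, so learned embeddings
separate identities poorly; a plain color histogram plus Pearson
correlation is used as a weak auxiliary similarity.  Histograms are
per-channel intensity histograms of the bounding-box crop, concatenated
and L1-normalized (default 3 channels x 16 bins).
"""

from __future__ import annotations

import numpy as np

DEFAULT_BINS_PER_CHANNEL = 16


class AppearanceError(ValueError):
    pass


def bbox_histogram(
    image: np.ndarray,
    bbox: tuple[float, float, float, float],
    bins_per_channel: int = DEFAULT_BINS_PER_CHANNEL,
    value_range: tuple[float, float] = (0.0, 256.0),
) -> np.ndarray:
    """Concatenated per-channel histogram of a bounding-box crop, L1-normalized.

    `image` is an (H, W) or (H, W, C) array; `bbox` is (x_min, y_min,
    width, height) in pixels.  The bbox is clipped to the image; an empty
    intersection is an error.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[:, :, None]
    h, w = img.shape[:2]
    x0 = max(int(np.floor(bbox[0])), 0)
    y0 = max(int(np.floor(bbox[1])), 0)
    x1 = min(int(np.ceil(bbox[0] + bbox[2])), w)
    y1 = min(int(np.ceil(bbox[1] + bbox[3])), h)
    if x1 <= x0 or y1 <= y0:
        raise AppearanceError(f"bbox {bbox} does not intersect image of shape {image.shape}")
    crop = img[y0:y1, x0:x1]
    parts = [np.histogram(crop[:, :, c], bins=bins_per_channel, range=value_range)[0]
             for c in range(crop.shape[2])]
    hist = np.concatenate(parts).astype(float)
    total = hist.sum()
    if total > 0:
        hist /= total
    return hist


def histogram_correlation(h1: np.ndarray, h2: np.ndarray) -> float:
    """Pearson correlation between two histograms' bin values, in [-1, 1].

    If either histogram has zero variance (e.g. the all-zero placeholder of
    a detection without appearance data) the similarity is defined as 0, so
    degenerate histograms never pass a positive similarity gate.
    """
    a = np.asarray(h1, dtype=float)
    b = np.asarray(h2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AppearanceError(f"histogram length mismatch: {a.shape} vs {b.shape}")
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0.0:
        return 0.0
    return float(np.clip((ac @ bc) / denom, -1.0, 1.0))


def mean_histogram(histograms: list[np.ndarray | None]) -> np.ndarray | None:
    """Arithmetic mean of member histograms, re-normalized to sum 1.

    Entries that are None are skipped; returns None if nothing remains.
    """
    hs = [np.asarray(h, dtype=float) for h in histograms if h is not None]
    if not hs:
        return None
    m = np.mean(hs, axis=0)
    total = m.sum()
    if total > 0:
        m = m / total
    return m
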