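"""Tracking and re-identification evaluation: MOTA, IDF1 and NMI.

Ground truth and predictions are compared on the ground plane.  Per-frame
correspondences use the CLEAR convention: a match from the previous frame
persists while the pair stays within the threshold, and remaining objects
are matched by a minimum-total-distance assignment gated at the
threshold.  MOTA aggregates misses, false positives and identity
switches; IDF1 scores the globally optimal one-to-one mapping between
ground-truth and predicted identities; NMI measures agreement of the two
identity labelings over matched detections, which is the natural score
for ReID treated as a clustering problem.

Ground truth may be sparse (e.g. annotated once per second): metrics are
computed only on annotated frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

# A point set indexed by frame: frame -> list of (identity, x_cm, y_cm).
FrameIndexed = Mapping[int, Sequence[tuple[int, float, float]]]


class MetricError(ValueError):
    """Metric undefined for this input (e.g. empty ground truth)."""


@dataclass(frozen=True)
class MOTAResult:
    FN: int
    FP: int
    IDSW: int
    GT: int

    @property
    def mota(self) -> float:
        return 1.0 - (self.FN + self.FP + self.IDSW) / self.GT


@dataclass(frozen=True)
class IDF1Result:
    IDTP: int
    IDFP: int
    IDFN: int

    @property
    def idf1(self) -> float:
        denom = 2 * self.IDTP + self.IDFP + self.IDFN
        return 2 * self.IDTP / denom if denom else 0.0


@dataclass
class IDVectors:
    """Aligned ground-truth and predicted identity sequences, one entry per
    matched detection; coverage is the matched fraction of GT instances."""

    label: list[int] = field(default_factory=list)
    prediction: list[int] = field(default_factory=list)
    coverage: float = 0.0

    def extend(self, other: "IDVectors") -> None:
        self.label.extend(other.label)
        self.prediction.extend(other.prediction)


def _frames_of(gt: FrameIndexed, frames: Optional[Sequence[int]]) -> list[int]:
    return sorted(gt.keys()) if frames is None else sorted(frames)


def match_frames(
    gt: FrameIndexed,
    pred: FrameIndexed,
    match_threshold_cm: float = 100.0,
    frames: Optional[Sequence[int]] = None,
) -> dict[int, list[tuple[int, int]]]:
    """Per-frame one-to-one (gt_id, pred_id) correspondences.

    Matches persist from the previous evaluated frame while both members
    are present and within threshold; the rest are matched by
    minimum-total-distance assignment, gated at the threshold.
    """
    matches: dict[int, list[tuple[int, int]]] = {}
    prev: dict[int, int] = {}  # gt_id -> pred_id carried over
    for f in _frames_of(gt, frames):
        gts = list(gt.get(f, ()))
        prs = list(pred.get(f, ()))
        gpos = {g: (x, y) for g, x, y in gts}
        ppos = {p: (x, y) for p, x, y in prs}
        cur: list[tuple[int, int]] = []
        used_g: set[int] = set()
        used_p: set[int] = set()
        # persist previous pairings still valid
        for g, p in prev.items():
            if g in gpos and p in ppos:
                if math.dist(gpos[g], ppos[p]) <= match_threshold_cm:
                    cur.append((g, p))
                    used_g.add(g)
                    used_p.add(p)
        rem_g = [g for g, _, _ in gts if g not in used_g]
        rem_p = [p for p, _, _ in prs if p not in used_p]
        if rem_g and rem_p:
            cost = np.array([[math.dist(gpos[g], ppos[p]) for p in rem_p]
                             for g in rem_g])
            feasible = cost <= match_threshold_cm
            if feasible.any():
                big = cost.sum() + match_threshold_cm * (len(rem_g) + len(rem_p)) + 1.0
                rows, cols = linear_sum_assignment(np.where(feasible, cost, big))
                for i, j in zip(rows, cols):
                    if feasible[i, j]:
                        cur.append((rem_g[i], rem_p[j]))
        cur.sort()
        matches[f] = cur
        prev = dict(cur)
    return matches


def mota(
    gt: FrameIndexed,
    pred: FrameIndexed,
    match_threshold_cm: float = 100.0,
    frames: Optional[Sequence[int]] = None,
) -> MOTAResult:
    """Multiple Object Tracking Accuracy: 1 - (FN + FP + IDSW) / GT.

    FN counts unmatched ground-truth instances, FP unmatched predictions,
    IDSW matched ground-truth objects whose predicted identity differs
    from the predicted identity at their previous match.  Can be negative;
    at most 1.
    """
    eval_frames = _frames_of(gt, frames)
    n_gt = sum(len(gt.get(f, ())) for f in eval_frames)
    if n_gt == 0:
        raise MetricError("MOTA undefined: ground truth is empty")
    matches = match_frames(gt, pred, match_threshold_cm, eval_frames)
    fn = fp = idsw = 0
    last_pred_of: dict[int, int] = {}
    for f in eval_frames:
        m = matches[f]
        matched_g = {g for g, _ in m}
        matched_p = {p for _, p in m}
        fn += sum(1 for g, _, _ in gt.get(f, ()) if g not in matched_g)
        fp += sum(1 for p, _, _ in pred.get(f, ()) if p not in matched_p)
        for g, p in m:
            if g in last_pred_of and last_pred_of[g] != p:
                idsw += 1
            last_pred_of[g] = p
    return MOTAResult(FN=fn, FP=fp, IDSW=idsw, GT=n_gt)


def idf1(
    gt: FrameIndexed,
    pred: FrameIndexed,
    match_threshold_cm: float = 100.0,
    frames: Optional[Sequence[int]] = None,
) -> IDF1Result:
    """Identification F1: F1 of the globally optimal one-to-one identity
    mapping, with per-pair matched-frame counts as the overlap measure."""
    eval_frames = _frames_of(gt, frames)
    n_gt = sum(len(gt.get(f, ())) for f in eval_frames)
    if n_gt == 0:
        raise MetricError("IDF1 undefined: ground truth is empty")
    n_pred = sum(len(pred.get(f, ())) for f in eval_frames)

    # overlap[g][p] = number of frames where g and p co-occur within threshold
    overlap: dict[tuple[int, int], int] = {}
    for f in eval_frames:
        gts = gt.get(f, ())
        prs = pred.get(f, ())
        for g, gx, gy in gts:
            for p, px, py in prs:
                if math.dist((gx, gy), (px, py)) <= match_threshold_cm:
                    overlap[(g, p)] = overlap.get((g, p), 0) + 1
    if not overlap:
        return IDF1Result(IDTP=0, IDFP=n_pred, IDFN=n_gt)
    g_ids = sorted({g for g, _ in overlap})
    p_ids = sorted({p for _, p in overlap})
    gain = np.zeros((len(g_ids), len(p_ids)))
    for (g, p), c in overlap.items():
        gain[g_ids.index(g), p_ids.index(p)] = c
    rows, cols = linear_sum_assignment(-gain)
    idtp = int(gain[rows, cols].sum())
    return IDF1Result(IDTP=idtp, IDFP=n_pred - idtp, IDFN=n_gt - idtp)


def build_id_vectors(
    gt: FrameIndexed,
    pred: FrameIndexed,
    matching: Mapping[int, Sequence[tuple[int, int]]],
    frames: Optional[Sequence[int]] = None,
) -> IDVectors:
    """Flatten per-frame matches into aligned (label, prediction) vectors,
    frames ascending.  Unmatched ground truth is excluded and reflected in
    the coverage ratio instead, so NMI scores identity consistency rather
    than detection recall."""
    eval_frames = _frames_of(gt, frames)
    v = IDVectors()
    n_gt = 0
    for f in eval_frames:
        n_gt += len(gt.get(f, ()))
        for g, p in sorted(matching.get(f, ())):
            v.label.append(g)
            v.prediction.append(p)
    v.coverage = len(v.label) / n_gt if n_gt else 0.0
    return v


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi(vectors: IDVectors) -> float:
    """Normalized mutual information 2 I(L;P) / (H(L) + H(P)) of the two
    identity labelings, from empirical joint frequencies.

    Base-invariant (computed in nats).  When both labelings are constant
    the score is 1 (they trivially agree); when exactly one is constant it
    is 0.
    """
    if not vectors.label:
        raise MetricError("NMI undefined: empty identity vectors")
    label = np.asarray(vectors.label)
    pred = np.asarray(vectors.prediction)
    l_vals, l_idx = np.unique(label, return_inverse=True)
    p_vals, p_idx = np.unique(pred, return_inverse=True)
    joint = np.zeros((len(l_vals), len(p_vals)))
    np.add.at(joint, (l_idx, p_idx), 1.0)
    hl = _entropy(joint.sum(axis=1))
    hp = _entropy(joint.sum(axis=0))
    if hl == 0.0 and hp == 0.0:
        return 1.0
    if hl == 0.0 or hp == 0.0:
        return 0.0
    n = joint.sum()
    pj = joint / n
    pl = pj.sum(axis=1)
    pp = pj.sum(axis=0)
    outer = np.outer(pl, pp)
    mask = pj > 0
    mi = float((pj[mask] * np.log(pj[mask] / outer[mask])).sum())
    return float(np.clip(2.0 * mi / (hl + hp), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Report assembly over per-camera tables.

def evaluate_tracking(
    gt_by_camera: Mapping[str, FrameIndexed],
    pred_by_camera: Mapping[str, FrameIndexed],
    match_threshold_cm: float = 100.0,
) -> dict:
    """Per-camera MOTA/IDF1 plus a global NMI over all cameras.

    Cameras are processed in sorted order; the NMI vectors concatenate the
    matched detections of every camera.
    """
    report: dict = {"cameras": {}, "match_threshold_cm": match_threshold_cm}
    all_vectors = IDVectors()
    n_gt_total = 0
    n_matched_total = 0
    for cam in sorted(gt_by_camera):
        gt = gt_by_camera[cam]
        pred = pred_by_camera.get(cam, {})
        m = mota(gt, pred, match_threshold_cm)
        i = idf1(gt, pred, match_threshold_cm)
        matching = match_frames(gt, pred, match_threshold_cm)
        vec = build_id_vectors(gt, pred, matching)
        n_cam_gt = sum(len(v) for v in gt.values())
        n_gt_total += n_cam_gt
        n_matched_total += len(vec.label)
        all_vectors.extend(vec)
        report["cameras"][cam] = {
            "mota": m.mota, "FN": m.FN, "FP": m.FP, "IDSW": m.IDSW, "GT": m.GT,
            "idf1": i.idf1, "IDTP": i.IDTP, "IDFP": i.IDFP, "IDFN": i.IDFN,
            "coverage": vec.coverage,
        }
    all_vectors.coverage = n_matched_total / n_gt_total if n_gt_total else 0.0
    report["nmi"] = nmi(all_vectors) if all_vectors.label else None
    report["coverage"] = all_vectors.coverage
    return report
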