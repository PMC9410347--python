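"""Cross-camera re-identification by density-based trajectory clustering.

Trajectories from all cameras live on the same ground plane, so two
trajectories of the same person recorded by different cameras nearly
coincide.  A DBSCAN-style procedure exploits this: a trajectory long
enough (observed length above T21) is a *core* object; another trajectory
q is in the neighborhood of a core p when their mean ground distance over
common frames is below T22 and their appearance similarity (correlation
of mean histograms) is above T23.  Clusters grow by density-reachability
through cores; short or isolated trajectories end up as noise and are
afterwards reattached to the most plausible cluster — this is what
repairs tracklets broken by occlusion, using the more complete coverage
of other cameras as the bridge.  Within a cluster, two trajectories from
the same camera must not overlap in time (a person appears at most once
per camera frame).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .appearance import histogram_correlation
from .tracking import Trajectory


@dataclass(frozen=True)
class ReidConfig:
    """Clustering parameters.

    T21: core threshold, frames — a trajectory observed for strictly more
         frames is a core object (default 7200, half of a 4-minute 60 FPS
         recording).
    T22: neighborhood gate on mean ground distance, cm (default 120;
         deliberately looser than the tracking gate to absorb homography
         mapping error between cameras).
    T23: neighborhood gate on appearance similarity in [-1, 1]
         (default 0.6).
    O_min: minimum number of common observed frames for the mean distance
         between two trajectories to be considered defined (default 30).
    overlap_tolerance: shared frames allowed between two same-camera
         trajectories inside one cluster (default 0).
    core_length_mode: "observed" counts observed frames (robust to gaps);
         "span" uses last_frame - first_frame + 1.
    w_dist, w_sim: weights of the two terms in the noise-reassignment
         score.
    """

    T21: int = 7200
    T22: float = 120.0
    T23: float = 0.6
    O_min: int = 30
    overlap_tolerance: int = 0
    core_length_mode: str = "observed"
    w_dist: float = 1.0
    w_sim: float = 1.0

    def __post_init__(self) -> None:
        if self.T21 < 1:
            raise ValueError("T21 must be >= 1")
        if self.T22 <= 0:
            raise ValueError("T22 must be > 0")
        if not -1.0 <= self.T23 <= 1.0:
            raise ValueError("T23 must be in [-1, 1]")
        if self.O_min < 1:
            raise ValueError("O_min must be >= 1")
        if self.core_length_mode not in ("observed", "span"):
            raise ValueError("core_length_mode must be 'observed' or 'span'")

    @staticmethod
    def for_sequence(n_frames: int, core_fraction: float = 0.5, **kw) -> "ReidConfig":
        """Config with the core threshold expressed as a fraction of the
        sequence length (default: half the video)."""
        return ReidConfig(T21=max(1, int(core_fraction * n_frames)), **kw)


@dataclass
class IdentityClustering:
    """Partition of trajectories into global identities.

    clusters[i] holds the member trajectories of global identity i; noise
    holds trajectories left unassigned by the density clustering (empty
    after reassign_noise).
    """

    clusters: list[list[Trajectory]] = field(default_factory=list)
    noise: list[Trajectory] = field(default_factory=list)

    def assignment(self) -> dict[tuple[str, int], int]:
        return assign_global_ids(self)


def temporal_length(t: Trajectory, cfg: ReidConfig) -> int:
    if cfg.core_length_mode == "span":
        return t.last_frame - t.first_frame + 1
    return t.observed_length


def is_core(t: Trajectory, cfg: ReidConfig) -> bool:
    """Core objects are trajectories strictly longer than T21 frames."""
    return temporal_length(t, cfg) > cfg.T21


def trajectory_affinity(
    p: Trajectory, q: Trajectory, cfg: ReidConfig
) -> tuple[Optional[float], float, int]:
    """(mean_distance, similarity, overlap) between two trajectories.

    The mean ground distance is taken over common observed frames and is
    undefined (None) when fewer than O_min frames are shared — temporally
    disjoint trajectories have no meaningful distance.  The appearance
    similarity compares the two trajectories' mean histograms and is
    defined regardless of temporal overlap, which is what lets broken
    same-camera fragments relate to each other through a cluster.
    """
    common = p.points.keys() & q.points.keys()
    overlap = len(common)
    if overlap >= cfg.O_min:
        d = 0.0
        for f in common:
            d += p.points[f].distance_to(q.points[f])
        mean_distance: Optional[float] = d / overlap
    else:
        mean_distance = None
    if p.mean_histogram is None or q.mean_histogram is None:
        similarity = 0.0
    else:
        similarity = histogram_correlation(p.mean_histogram, q.mean_histogram)
    return mean_distance, similarity, overlap


def _is_neighbor(affinity: tuple[Optional[float], float, int], cfg: ReidConfig) -> bool:
    mean_distance, similarity, _ = affinity
    return (mean_distance is not None and mean_distance < cfg.T22
            and similarity > cfg.T23)


def _shared_frames(a: Trajectory, b: Trajectory) -> int:
    return len(a.points.keys() & b.points.keys())


def _violates_overlap_rule(t: Trajectory, members: Sequence[Trajectory],
                           cfg: ReidConfig) -> bool:
    for m in members:
        if m.camera_id == t.camera_id and _shared_frames(t, m) > cfg.overlap_tolerance:
            return True
    return False


def _sort_key(cfg: ReidConfig):
    return lambda t: (-temporal_length(t, cfg), t.camera_id, t.local_id)


def cluster_trajectories(
    trajs: Sequence[Trajectory], cfg: ReidConfig
) -> IdentityClustering:
    """Density-based clustering of trajectories into identities.

    Cores are processed in descending temporal length (ties broken by
    camera_id then local_id).  Each unassigned core seeds a cluster; the
    cluster expands by breadth-first density-reachability through core
    members only — border (non-core) trajectories join the first cluster
    that reaches them but never expand it.  Adding a trajectory that would
    put two temporally overlapping same-camera trajectories in one cluster
    is rejected; whatever remains unassigned is the noise set.
    """
    trajs = list(trajs)
    n = len(trajs)
    neighbor = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            aff = trajectory_affinity(trajs[i], trajs[j], cfg)
            neighbor[i, j] = neighbor[j, i] = _is_neighbor(aff, cfg)

    order = sorted(range(n), key=lambda i: _sort_key(cfg)(trajs[i]))
    core = [is_core(t, cfg) for t in trajs]
    assigned = [False] * n
    clustering = IdentityClustering()

    for seed in order:
        if not core[seed] or assigned[seed]:
            continue
        members: list[Trajectory] = [trajs[seed]]
        member_idx = [seed]
        assigned[seed] = True
        rejected: set[int] = set()
        queue = [seed]
        while queue:
            c = queue.pop(0)
            cands = [j for j in range(n) if neighbor[c][j]
                     and not assigned[j] and j not in rejected]
            cands.sort(key=lambda j: _sort_key(cfg)(trajs[j]))
            for j in cands:
                if _violates_overlap_rule(trajs[j], members, cfg):
                    rejected.add(j)
                    continue
                assigned[j] = True
                members.append(trajs[j])
                member_idx.append(j)
                if core[j]:
                    queue.append(j)
        clustering.clusters.append(members)

    clustering.noise = [trajs[i] for i in range(n) if not assigned[i]]
    return clustering


def _cluster_affinity(
    t: Trajectory, members: Sequence[Trajectory], cfg: ReidConfig
) -> tuple[Optional[float], float]:
    """Mean distance (over members with a defined pairwise distance) and
    mean similarity between a trajectory and a cluster."""
    dists = []
    sims = []
    for m in members:
        mean_distance, similarity, _ = trajectory_affinity(t, m, cfg)
        sims.append(similarity)
        if mean_distance is not None:
            dists.append(mean_distance)
    dist = float(np.mean(dists)) if dists else None
    sim = float(np.mean(sims)) if sims else 0.0
    return dist, sim


def reassign_noise(clustering: IdentityClustering, cfg: ReidConfig) -> IdentityClustering:
    """Attach each noise trajectory to its most plausible cluster.

    Noise trajectories are processed in descending temporal length.  A
    cluster is a candidate when the mean similarity exceeds T23, the mean
    distance (when defined for at least one member) is below T22, and the
    same-camera overlap rule holds after insertion; a cluster with no
    temporally overlapping member may still be a candidate on similarity
    alone, which is the bridge that reattaches occlusion-broken fragments.
    Among candidates the one minimizing

        w_dist * (dist / T22, or 1 if undefined) - w_sim * sim

    wins; with no candidate the trajectory becomes a fresh singleton
    cluster.  Later noise trajectories see earlier reassignments.
    """
    result = IdentityClustering(clusters=[list(c) for c in clustering.clusters])
    for t in sorted(clustering.noise, key=_sort_key(cfg)):
        best: Optional[int] = None
        best_score = math.inf
        for ci, members in enumerate(result.clusters):
            dist, sim = _cluster_affinity(t, members, cfg)
            if sim <= cfg.T23:
                continue
            if dist is not None and dist >= cfg.T22:
                continue
            if _violates_overlap_rule(t, members, cfg):
                continue
            score = cfg.w_dist * (dist / cfg.T22 if dist is not None else 1.0) \
                - cfg.w_sim * sim
            if score < best_score:
                best_score = score
                best = ci
        if best is None:
            result.clusters.append([t])
        else:
            result.clusters[best].append(t)
    return result


def assign_global_ids(clustering: IdentityClustering) -> dict[tuple[str, int], int]:
    """Dense integer global ids in cluster order; noise trajectories (if
    reassignment was skipped) get fresh singleton ids after the clusters."""
    out: dict[tuple[str, int], int] = {}
    gid = 0
    for members in clustering.clusters:
        for t in members:
            out[(t.camera_id, t.local_id)] = gid
        gid += 1
    for t in clustering.noise:
        out[(t.camera_id, t.local_id)] = gid
        gid += 1
    return out


def reidentify(trajs: Sequence[Trajectory], cfg: ReidConfig) -> tuple[IdentityClustering, dict[tuple[str, int], int]]:
    """Cluster, reassign noise, and label: the full ReID stage."""
    clustering = reassign_noise(cluster_trajectories(trajs, cfg), cfg)
    return clustering, assign_global_ids(clustering)
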