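"""Trajectory clustering for cross-camera re-identification."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ortrack.geometry import GroundPoint
from ortrack.reid import (IdentityClustering, ReidConfig, assign_global_ids,
                          cluster_trajectories, is_core, reassign_noise,
                          reidentify, trajectory_affinity)
from ortrack.tracking import Trajectory
from .conftest import make_trajectory, peaked_histogram


CFG = ReidConfig(T21=50, T22=120.0, T23=0.6, O_min=10)


class TestAffinity:
    def test_self_affinity(self):
        t = make_trajectory("cam0", 0, list(range(100)), (10.0, 20.0),
                            histogram=peaked_histogram(3))
        d, s, o = trajectory_affinity(t, t, CFG)
        assert d == 0.0 and s == pytest.approx(1.0) and o == 100

    def test_disjoint_distance_undefined_similarity_defined(self):
        a = make_trajectory("cam0", 0, list(range(0, 50)), (0.0, 0.0),
                            histogram=peaked_histogram(3))
        b = make_trajectory("cam1", 0, list(range(100, 150)), (0.0, 0.0),
                            histogram=peaked_histogram(3))
        d, s, o = trajectory_affinity(a, b, CFG)
        assert d is None and o == 0 and s == pytest.approx(1.0)

    def test_parallel_lines_constant_offset(self):
        frames = list(range(60))
        a = make_trajectory("cam0", 0, frames, [(float(f), 0.0) for f in frames])
        b = make_trajectory("cam1", 0, frames, [(float(f), 50.0) for f in frames])
        d, _, o = trajectory_affinity(a, b, CFG)
        assert d == pytest.approx(50.0) and o == 60

    def test_overlap_below_minimum_undefined(self):
        a = make_trajectory("cam0", 0, list(range(0, 20)), (0.0, 0.0))
        b = make_trajectory("cam1", 0, list(range(15, 40)), (0.0, 0.0))
        d, _, o = trajectory_affinity(a, b, ReidConfig(T21=50, O_min=10))
        assert o == 5 and d is None


class TestIsCore:
    @pytest.mark.parametrize("length, t21, core", [
        (7201, 7200, True),   # strictly greater than the threshold
        (7200, 7200, False),
        (10, 5, True),
    ])
    def test_strict_boundary(self, length, t21, core):
        t = make_trajectory("cam0", 0, list(range(length)), (0.0, 0.0))
        assert is_core(t, ReidConfig(T21=t21)) is core

    def test_span_mode_counts_gaps(self):
        frames = [0, 1, 2, 99]
        t = make_trajectory("cam0", 0, frames, (0.0, 0.0))
        assert not is_core(t, ReidConfig(T21=50))
        assert is_core(t, ReidConfig(T21=50, core_length_mode="span"))


def co_located(camera: str, lid: int, n: int, xy, peak: int = 0,
               start: int = 0) -> Trajectory:
    return make_trajectory(camera, lid, list(range(start, start + n)), xy,
                           histogram=peaked_histogram(peak))


class TestClusterTrajectories:
    def test_three_cameras_one_person(self):
        ts = [co_located(f"cam{i}", 0, 100, (100.0, 100.0)) for i in range(3)]
        c = cluster_trajectories(ts, CFG)
        assert len(c.clusters) == 1 and len(c.clusters[0]) == 3 and not c.noise

    def test_two_distant_groups(self):
        near = [co_located(f"cam{i}", 0, 100, (0.0, 0.0)) for i in range(2)]
        far = [co_located(f"cam{i}", 1, 100, (500.0, 500.0)) for i in range(2)]
        c = cluster_trajectories(near + far, CFG)
        assert len(c.clusters) == 2
        assert {len(cl) for cl in c.clusters} == {2}

    def test_border_joins_but_cannot_seed(self):
        core = co_located("cam0", 0, 100, (0.0, 0.0))
        border = co_located("cam1", 0, 20, (10.0, 0.0))  # too short to be core
        c = cluster_trajectories([core, border], CFG)
        assert len(c.clusters) == 1 and len(c.clusters[0]) == 2
        c2 = cluster_trajectories([border], CFG)
        assert not c2.clusters and c2.noise == [border]

    def test_appearance_gate_blocks_neighborhood(self):
        a = co_located("cam0", 0, 100, (0.0, 0.0), peak=0)
        b = co_located("cam1", 0, 100, (0.0, 0.0), peak=20)  # different uniform
        c = cluster_trajectories([a, b], CFG)
        assert len(c.clusters) == 2  # both core, not neighbors

    def test_same_camera_overlap_rejected(self):
        a = co_located("cam0", 0, 100, (0.0, 0.0))
        b = co_located("cam1", 0, 100, (5.0, 0.0))
        dup = co_located("cam0", 1, 100, (8.0, 0.0))  # same camera, same time
        c = cluster_trajectories([a, b, dup], CFG)
        sizes = sorted(len(cl) for cl in c.clusters)
        total_noise = len(c.noise)
        # dup cannot share a cluster with a; it seeds its own or stays noise
        for cl in c.clusters:
            cams_frames = [(t.camera_id, frozenset(t.points)) for t in cl]
            for i in range(len(cams_frames)):
                for j in range(i + 1, len(cams_frames)):
                    if cams_frames[i][0] == cams_frames[j][0]:
                        assert not (cams_frames[i][1] & cams_frames[j][1])
        assert sizes[-1] == 2 and (total_noise == 1 or len(c.clusters) == 2)


# ---------------------------------------------------------------------------
# Exhaustive density-reachability oracle: neighbor relation recomputed from
# scratch, core components found by sparse connected components, borders
# attached to the earliest-seeded adjacent cluster.

def oracle_cluster(trajs, cfg):
    n = len(trajs)

    def neighbor(a, b):
        common = sorted(a.points.keys() & b.points.keys())
        if len(common) < cfg.O_min:
            return False
        d = np.mean([np.hypot(a.points[f].X - b.points[f].X,
                              a.points[f].Y - b.points[f].Y) for f in common])
        sim = np.corrcoef(a.mean_histogram, b.mean_histogram)[0, 1]
        return d < cfg.T22 and sim > cfg.T23

    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            adj[i, j] = adj[j, i] = neighbor(trajs[i], trajs[j])
    cores = [i for i in range(n) if trajs[i].observed_length > cfg.T21]
    if not cores:
        return [], set(range(n))
    sub = adj[np.ix_(cores, cores)]
    n_comp, labels = connected_components(csr_matrix(sub), directed=False)
    comps = [[cores[i] for i in range(len(cores)) if labels[i] == k]
             for k in range(n_comp)]
    # order clusters by their longest core (desc), ties by camera then id
    def key(comp):
        best = min(comp, key=lambda i: (-trajs[i].observed_length,
                                        trajs[i].camera_id, trajs[i].local_id))
        t = trajs[best]
        return (-t.observed_length, t.camera_id, t.local_id)

    comps.sort(key=key)
    clusters = [set(c) for c in comps]
    core_set = set(cores)
    for b in range(n):
        if b in core_set:
            continue
        for cl in clusters:
            if any(adj[b, c] for c in cl & core_set):
                cl.add(b)
                break
    noise = set(range(n)) - set().union(*clusters)
    return [frozenset(c) for c in clusters], noise


def random_config(seed):
    """Up to 10 trajectories on distinct cameras with mixed lengths,
    locations and uniform classes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 11))
    cfg = ReidConfig(T21=50, T22=120.0, T23=0.6, O_min=10)
    centers = rng.uniform(0, 400, (3, 2))
    trajs = []
    for i in range(n):
        length = int(rng.integers(5, 200))
        start = int(rng.integers(0, 100))
        c = centers[rng.integers(0, 3)] + rng.normal(0, 30, 2)
        frames = list(range(start, start + length))
        pts = [tuple(c + rng.normal(0, 5, 2)) for _ in frames]
        t = make_trajectory(f"cam{i}", i, frames, pts,
                            histogram=peaked_histogram(
                                int(rng.integers(0, 3)) * 16,
                                minor=float(rng.uniform(0.05, 0.2))))
        trajs.append(t)
    return trajs, cfg


@pytest.mark.parametrize("seed", range(100))
def test_clustering_matches_exhaustive_oracle(seed):
    trajs, cfg = random_config(seed)
    got = cluster_trajectories(trajs, cfg)
    got_clusters = [frozenset(trajs.index(t) for t in cl) for cl in got.clusters]
    got_noise = {trajs.index(t) for t in got.noise}
    want_clusters, want_noise = oracle_cluster(trajs, cfg)
    assert got_clusters == want_clusters
    assert got_noise == want_noise


class TestReassignNoise:
    def test_broken_tracklet_bridged_by_other_camera(self):
        # same-camera tracklet broken in two, full-length core elsewhere
        path = [(float(100 + 0.01 * f), 200.0) for f in range(14_400)]
        core = make_trajectory("cam1", 0, list(range(14_400)), path,
                               histogram=peaked_histogram(0))
        seg1 = make_trajectory("cam0", 0, list(range(0, 4001)), path[:4001],
                               histogram=peaked_histogram(0))
        seg2 = make_trajectory("cam0", 1, list(range(4200, 14_400)),
                               path[4200:], histogram=peaked_histogram(0))
        cfg = ReidConfig(T21=7200, T22=120.0, T23=0.6, O_min=30)
        _, gids = reidentify([core, seg1, seg2], cfg)
        assert gids[("cam0", 0)] == gids[("cam1", 0)]
        assert gids[("cam0", 1)] == gids[("cam1", 0)]

    def test_distant_noise_becomes_singleton(self):
        core = co_located("cam0", 0, 100, (0.0, 0.0))
        far = co_located("cam1", 0, 20, (1000.0, 1000.0))  # same uniform
        clustering = cluster_trajectories([core, far], CFG)
        assert far in clustering.noise
        final = reassign_noise(clustering, CFG)
        assert [len(c) for c in final.clusters] == [1, 1]

    def test_same_camera_overlap_forces_next_best(self):
        core_a = co_located("cam1", 0, 100, (0.0, 0.0))
        dup = co_located("cam1", 1, 30, (3.0, 0.0))  # overlaps core_a in time
        clustering = cluster_trajectories([core_a, dup], CFG)
        assert dup in clustering.noise
        final = reassign_noise(clustering, CFG)
        # cannot join core_a's cluster: overlap rule; becomes singleton
        assert sorted(len(c) for c in final.clusters) == [1, 1]

    def test_dissimilar_noise_not_attached(self):
        core = co_located("cam0", 0, 100, (0.0, 0.0), peak=0)
        odd = co_located("cam1", 0, 20, (0.0, 0.0), peak=20)
        final = reassign_noise(cluster_trajectories([core, odd], CFG), CFG)
        assert sorted(len(c) for c in final.clusters) == [1, 1]


class TestGlobalIds:
    def test_dense_ids(self):
        a = co_located("cam0", 0, 100, (0.0, 0.0))
        b = co_located("cam1", 0, 100, (2.0, 0.0))
        far = co_located("cam2", 0, 100, (500.0, 500.0), peak=20)
        single = co_located("cam3", 0, 20, (900.0, 100.0), peak=40)
        _, gids = reidentify([a, b, far, single], CFG)
        assert sorted(set(gids.values())) == [0, 1, 2]
        assert gids[("cam0", 0)] == gids[("cam1", 0)]

    def test_empty_input(self):
        clustering, gids = reidentify([], CFG)
        assert gids == {} and clustering.clusters == []

    def test_deterministic(self):
        trajs, cfg = random_config(5)
        a = reidentify(trajs, cfg)[1]
        b = reidentify(trajs, cfg)[1]
        assert a == b


class TestPartitionInvariants:
    @pytest.mark.parametrize("seed", range(20))
    def test_every_trajectory_labeled_once_and_overlap_rule_holds(self, seed):
        rng = np.random.default_rng(seed)
        trajs, cfg = random_config(seed)
        # force camera collisions so the overlap rule is exercised
        for t in trajs:
            t.camera_id = f"cam{rng.integers(0, 3)}"
        clustering, gids = reidentify(trajs, cfg)
        assert len(gids) == len(trajs)
        assert not clustering.noise
        for cl in clustering.clusters:
            for i in range(len(cl)):
                for j in range(i + 1, len(cl)):
                    if cl[i].camera_id == cl[j].camera_id:
                        shared = cl[i].points.keys() & cl[j].points.keys()
                        assert len(shared) <= cfg.overlap_tolerance
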