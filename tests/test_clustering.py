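"""Pose clustering: metrics, adaptive k selection and the population gate."""

import itertools

import numpy as np
import pytest

from enscreen.clustering import (cluster_adaptive, dbi, pose_rmsd_matrix,
                                 pvariance, representative_cluster)
from enscreen.simulate import make_pose_cloud

from conftest import pose_from_coords


def dist_from_points(points):
    points = np.asarray(points, dtype=float).reshape(len(points), -1)
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def exhaustive_best_dbi(dist, k):
    """Minimum DBI over every partition of n items into k non-empty parts."""
    n = dist.shape[0]
    best = np.inf

    def partitions(items, k):
        if k == 1:
            yield [items]
            return
        if len(items) == k:
            yield [[i] for i in items]
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest, k - 1):
            yield [[first]] + part
        for part in partitions(rest, k):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]

    for part in partitions(list(range(n)), k):
        labels = np.empty(n, dtype=int)
        for c, members in enumerate(part):
            labels[members] = c
        try:
            best = min(best, dbi(dist, labels))
        except ValueError:
            continue
    return best


def test_dbi_two_singletons():
    d = dist_from_points([[0.0], [5.0]])
    assert dbi(d, [0, 1]) == pytest.approx(0.0, abs=1e-12)


def test_dbi_hand_computed_1d():
    # {0, 0.1} and {10, 10.1}: s_i = 0.05 each, medoid distance 10
    d = dist_from_points([[0.0], [0.1], [10.0], [10.1]])
    expected = (0.05 + 0.05) / 10.0
    assert dbi(d, [0, 0, 1, 1]) == pytest.approx(expected, rel=1e-9)


def test_dbi_requires_two_clusters():
    d = dist_from_points([[0.0], [1.0]])
    with pytest.raises(ValueError, match="2 clusters"):
        dbi(d, [0, 0])


def test_dbi_coincident_medoids_error():
    d = dist_from_points([[0.0], [0.0], [0.0], [0.0]])
    with pytest.raises(ValueError, match="coincident"):
        dbi(d, [0, 0, 1, 1])


def test_pvariance_all_singletons_and_k1():
    d = dist_from_points([[0.0], [1.0], [3.0]])
    assert pvariance(d, [0, 1, 2]) == pytest.approx(100.0)
    assert pvariance(d, [0, 0, 0]) == pytest.approx(0.0)


def test_pvariance_identical_poses():
    d = np.zeros((3, 3))
    assert pvariance(d, [0, 0, 0]) == 100.0


def test_pvariance_matches_direct_computation(rng):
    cloud = make_pose_cloud(5, k_true=3, n=30)
    d = pose_rmsd_matrix(cloud["poses"])
    labels = cloud["labels"]
    # direct SSR/SST with medoid references, written independently
    def medoid(members):
        sub = d[np.ix_(members, members)]
        return members[int(np.argmin(sub.sum(axis=1)))]
    g = medoid(np.arange(len(labels)))
    sst = float(np.sum(d[:, g] ** 2))
    ssr = 0.0
    for c in range(3):
        members = np.flatnonzero(labels == c)
        m = medoid(members)
        ssr += float(np.sum(d[members, m] ** 2))
    assert pvariance(d, labels) == pytest.approx(100 * (1 - ssr / sst),
                                                 rel=1e-12)


def test_adaptive_two_planted_groups():
    cloud = make_pose_cloud(3, k_true=2, n=30, intra_spread=0.1,
                            separation=10.0)
    sol = cluster_adaptive(pose_rmsd_matrix(cloud["poses"]),
                           energies=cloud["energies"])
    assert sol.k == 2
    # same partition as planted, up to label names
    mapping = {}
    for got, true in zip(sol.assignment, cloud["labels"]):
        mapping.setdefault(got, true)
        assert mapping[got] == true


def test_adaptive_matches_exhaustive_optimum():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        centers = rng.uniform(0, 40, size=2)
        while abs(centers[0] - centers[1]) < 10:
            centers = rng.uniform(0, 40, size=2)
        pts = np.concatenate([c + rng.normal(0, 0.3, size=4)
                              for c in centers])[:, None]
        d = dist_from_points(pts)
        sol = cluster_adaptive(d)
        assert sol.k >= 2
        assert sol.dbi == pytest.approx(exhaustive_best_dbi(d, sol.k),
                                        rel=1e-9)


def test_adaptive_unimodal_returns_trivial():
    cloud = make_pose_cloud(2, k_true=1, n=40, energy_offsets=[-7.0])
    sol = cluster_adaptive(pose_rmsd_matrix(cloud["poses"]),
                           energies=cloud["energies"])
    assert sol.k == 1
    assert sol.populations.tolist() == [40]
    assert sol.dbi is None
    rep = representative_cluster(sol, cloud["energies"])
    assert rep is not None and rep[0] == 0


def test_adaptive_needs_two_poses():
    with pytest.raises(ValueError):
        cluster_adaptive(np.zeros((1, 1)))


def test_matrix_validation():
    with pytest.raises(ValueError, match="square"):
        cluster_adaptive(np.zeros((2, 3)))
    bad = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        cluster_adaptive(bad)
    neg = np.array([[0.0, -1.0], [-1.0, 0.0]])
    with pytest.raises(ValueError, match="non-negative"):
        cluster_adaptive(neg)


def test_permutation_equivariance(rng):
    cloud = make_pose_cloud(7, k_true=3, n=24)
    d = pose_rmsd_matrix(cloud["poses"])
    base = cluster_adaptive(d)
    perm = rng.permutation(24)
    d2 = d[np.ix_(perm, perm)]
    sol2 = cluster_adaptive(d2)
    assert sol2.k == base.k
    # co-membership must be permuted identically
    co1 = base.assignment[:, None] == base.assignment[None, :]
    co2 = sol2.assignment[:, None] == sol2.assignment[None, :]
    assert np.array_equal(co2, co1[np.ix_(perm, perm)])


def test_dbi_decreases_with_separation():
    values = []
    for sep in (6.0, 12.0, 24.0):
        cloud = make_pose_cloud(11, k_true=2, n=30, intra_spread=0.4,
                                separation=sep)
        d = pose_rmsd_matrix(cloud["poses"])
        values.append(dbi(d, cloud["labels"]))
    assert values[0] > values[1] > values[2]


def test_pvariance_nondecreasing_in_nested_cuts():
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform
    cloud = make_pose_cloud(13, k_true=3, n=30)
    d = pose_rmsd_matrix(cloud["poses"])
    z = linkage(squareform(d, checks=False), method="average")
    pvs = [pvariance(d, fcluster(z, t=k, criterion="maxclust"))
           for k in range(1, 10)]
    assert all(b >= a - 1e-9 for a, b in zip(pvs, pvs[1:]))


def test_representative_single_cluster():
    cloud = make_pose_cloud(2, k_true=1, n=10, energy_offsets=[-7.7])
    energies = cloud["energies"].copy()
    energies[3] = -7.2
    d = pose_rmsd_matrix(cloud["poses"])
    sol = cluster_adaptive(d, energies=energies)
    rep = representative_cluster(sol, energies)
    assert rep == (0, pytest.approx(min(energies)))


def test_representative_gate_rejects_20_percent():
    cloud = make_pose_cloud(9, k_true=5, n=100, separation=15.0,
                            fractions=[0.2, 0.2, 0.2, 0.2, 0.2])
    d = pose_rmsd_matrix(cloud["poses"])
    sol = cluster_adaptive(d, energies=cloud["energies"])
    assert sol.k == 5
    assert representative_cluster(sol, cloud["energies"],
                                  min_population=0.25) is None


def test_gate_inclusive_at_exactly_25_percent():
    cloud = make_pose_cloud(17, k_true=4, n=100, separation=15.0,
                            fractions=[0.25, 0.25, 0.25, 0.25])
    d = pose_rmsd_matrix(cloud["poses"])
    sol = cluster_adaptive(d, energies=cloud["energies"])
    assert sol.populations.max() == 25
    assert representative_cluster(sol, cloud["energies"],
                                  min_population=0.25) is not None


def test_representative_matches_direct_oracle(rng):
    cloud = make_pose_cloud(21, k_true=3, n=60,
                            fractions=[0.5, 0.3, 0.2])
    d = pose_rmsd_matrix(cloud["poses"])
    sol = cluster_adaptive(d, energies=cloud["energies"])
    rep = representative_cluster(sol, cloud["energies"], min_population=0.0)
    # independent argmax-population then min-energy oracle
    pops = [np.sum(sol.assignment == c) for c in range(sol.k)]
    biggest = int(np.argmax(pops))
    oracle_energy = float(cloud["energies"][sol.assignment == biggest].min())
    assert rep == (biggest, pytest.approx(oracle_energy))


def test_representative_needs_energies():
    cloud = make_pose_cloud(2, k_true=1, n=6)
    sol = cluster_adaptive(pose_rmsd_matrix(cloud["poses"]))
    with pytest.raises(ValueError, match="energies"):
        representative_cluster(sol)
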