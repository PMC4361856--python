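import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from memglyco.clustering import (DistanceMatrix, average_linkage, core_rmsd,
                                 kabsch_superpose, representatives,
                                 rmsd_matrix)
from memglyco.errors import InsufficientDataError
from memglyco.model_io import Frame, Trajectory
from memglyco.synthetic import csf114_helix, make_cluster_fixture


def numeric_rmsd_oracle(moving, reference):
    """Brute-force minimisation over rotation vector + translation."""
    moving = np.asarray(moving, float)
    reference = np.asarray(reference, float)

    def objective(x):
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        fitted = moving @ rot.T + x[3:]
        return np.sqrt(((fitted - reference) ** 2).sum() / len(reference))

    best = np.inf
    for x0 in ([0, 0, 0, 0, 0, 0], [1, 1, 1, 0, 0, 0], [-2, 0.5, 1, 1, 1, 1]):
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000, "maxfev": 20000})
        best = min(best, res.fun)
    return best


def exhaustive_average_linkage(square, n_clusters):
    """Reference agglomeration recomputing every inter-cluster average from
    the raw matrix at each step; same id scheme and tie-break as the
    implementation."""
    k = len(square)
    clusters = {i: [i] for i in range(k)}
    merges = []
    next_id = k
    cut = None
    while len(clusters) > 1:
        best = None
        for ci, cj in itertools.combinations(sorted(clusters), 2):
            dij = np.mean([square[a, b] for a in clusters[ci]
                           for b in clusters[cj]])
            key = (dij, ci, cj)
            if best is None or key < best:
                best = key
        dij, ci, cj = best
        merges.append((ci, cj, dij, len(clusters[ci]) + len(clusters[cj])))
        clusters[next_id] = clusters.pop(ci) + clusters.pop(cj)
        next_id += 1
        if len(clusters) == n_clusters:
            cut = [sorted(v) for v in clusters.values()]
    if cut is None:
        cut = [[i] for i in range(k)]
    labels = np.empty(k, dtype=int)
    for lbl, members in enumerate(sorted(cut, key=min)):
        labels[members] = lbl
    return np.array(merges, dtype=float), labels


def canon(labels):
    seen = {}
    return tuple(seen.setdefault(x, len(seen)) for x in labels)


class TestKabsch:
    def test_self_superposition_zero(self, rng):
        pts = rng.normal(size=(8, 3))
        _, _, rmsd = kabsch_superpose(pts, pts)
        assert rmsd <= 1e-12

    def test_rigid_copy_recovered(self, rng):
        pts = rng.normal(size=(10, 3))
        rot = Rotation.from_rotvec([0.4, -0.9, 2.2]).as_matrix()
        moved = pts @ rot.T + np.array([3.0, -1.0, 8.0])
        r, t, rmsd = kabsch_superpose(moved, pts)
        assert rmsd <= 1e-10
        assert np.linalg.det(r) == pytest.approx(1.0)

    def test_displaced_point_matches_numeric_oracle(self, rng):
        ref = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3.0]])
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        moving = ref @ rot.T + np.array([2.0, 2.0, 2.0])
        moving[1] += rot @ np.array([1.0, 0, 0])  # 1 A displacement
        _, _, rmsd = kabsch_superpose(moving, ref)
        assert rmsd == pytest.approx(numeric_rmsd_oracle(moving, ref), abs=1e-6)

    def test_mismatched_or_degenerate_inputs(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        from memglyco.errors import DegenerateGeometryError
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


class TestCoreRmsd:
    def test_metric_sanity(self, csf114, rng):
        _, frame = csf114
        a = frame
        b = Frame(coordinates=frame.coordinates
                  + rng.normal(0, 0.5, frame.coordinates.shape))
        top, _ = csf114
        assert core_rmsd(a, a, top) < 1e-12
        assert core_rmsd(a, b, top) == pytest.approx(
            core_rmsd(b, a, top), abs=1e-10)

    def test_rigidly_moved_frame_is_zero(self, csf114):
        top, frame = csf114
        rot = Rotation.from_rotvec([0.1, 0.8, -0.3]).as_matrix()
        moved = Frame(coordinates=frame.coordinates @ rot.T + 5.0)
        assert core_rmsd(frame, moved, top) < 1e-10

    def test_single_displaced_core_atom_vs_oracle(self, csf114):
        top, frame = csf114
        pep = top.peptide()
        core_idx = np.array(pep.ca_indices(range(5, 13)))
        moved = frame.coordinates.copy()
        moved[core_idx[3]] += np.array([0, 0, 2.0])
        got = core_rmsd(frame, Frame(coordinates=moved), top)
        ref = numeric_rmsd_oracle(frame.coordinates[core_idx], moved[core_idx])
        assert got == pytest.approx(ref, abs=1e-6)


class TestRmsdMatrix:
    def test_identical_frames_all_zero(self, csf114):
        top, frame = csf114
        traj = Trajectory(topology=top, frames=[frame] * 3)
        m = rmsd_matrix(traj, np.ones(3, dtype=bool))
        assert np.all(m.condensed < 1e-7)

    def test_condensed_length(self, csf114, rng):
        top, frame = csf114
        frames = [Frame(coordinates=frame.coordinates
                        + rng.normal(0, 0.3, frame.coordinates.shape))
                  for _ in range(7)]
        traj = Trajectory(topology=top, frames=frames)
        m = rmsd_matrix(traj, np.ones(7, dtype=bool))
        assert len(m.condensed) == 7 * 6 // 2

    def test_entries_match_direct_core_rmsd(self, csf114, rng):
        top, frame = csf114
        frames = [Frame(coordinates=frame.coordinates
                        + rng.normal(0, 0.4, frame.coordinates.shape))
                  for _ in range(10)]
        traj = Trajectory(topology=top, frames=frames)
        m = rmsd_matrix(traj, np.ones(10, dtype=bool))
        square = m.square()
        for _ in range(20):
            i, j = rng.choice(10, 2, replace=False)
            assert square[i, j] == pytest.approx(
                core_rmsd(frames[i], frames[j], top), abs=1e-8)

    def test_too_few_bound_frames(self, csf114):
        top, frame = csf114
        traj = Trajectory(topology=top, frames=[frame] * 3)
        with pytest.raises(InsufficientDataError):
            rmsd_matrix(traj, np.array([True, False, False]))


class TestAverageLinkage:
    def test_two_observations_single_merge(self):
        m = DistanceMatrix(condensed=[2.5], frame_indices=[0, 1])
        res = average_linkage(m, 1)
        assert res.merges.shape == (1, 4)
        assert res.merges[0, 2] == pytest.approx(2.5)

    def test_exhaustive_oracle_small_matrices(self, rng):
        for trial in range(200):
            k = int(rng.integers(3, 7))
            if trial % 4 == 0:  # integer distances force ties
                cond = rng.integers(1, 5, k * (k - 1) // 2).astype(float)
            else:
                cond = rng.uniform(0.1, 10.0, k * (k - 1) // 2)
            m = DistanceMatrix(condensed=cond, frame_indices=np.arange(k))
            nc = int(rng.integers(1, k + 1))
            res = average_linkage(m, nc)
            ref_merges, ref_labels = exhaustive_average_linkage(m.square(), nc)
            assert np.array_equal(res.merges[:, :2], ref_merges[:, :2])
            assert np.allclose(res.merges[:, 2], ref_merges[:, 2])
            assert canon(res.labels) == canon(ref_labels)

    def test_scipy_cross_check(self, rng):
        for _ in range(30):
            k = int(rng.integers(5, 15))
            cond = rng.uniform(0.1, 10.0, k * (k - 1) // 2)
            m = DistanceMatrix(condensed=cond, frame_indices=np.arange(k))
            nc = int(rng.integers(1, k + 1))
            res = average_linkage(m, nc)
            z = linkage(cond, method="average")
            assert np.allclose(np.sort(res.merges[:, 2]), np.sort(z[:, 2]))
            assert canon(res.labels) == canon(fcluster(z, nc, "maxclust"))

    def test_heights_non_decreasing(self, rng):
        cond = rng.uniform(0.1, 10.0, 45)
        res = average_linkage(DistanceMatrix(condensed=cond,
                                             frame_indices=np.arange(10)), 1)
        assert np.all(np.diff(res.merges[:, 2]) >= -1e-12)

    def test_permutation_invariance(self, csf114, rng):
        top, frame = csf114
        traj, labels = make_cluster_fixture(
            40, [frame.coordinates, frame.coordinates + [0, 0, 6.0]],
            0.2, [0.5, 0.5], seed=11)
        m = rmsd_matrix(traj, np.ones(40, dtype=bool))
        res = average_linkage(m, 2)
        perm = rng.permutation(40)
        traj2 = Trajectory(topology=traj.topology,
                           frames=[traj.frames[i] for i in perm])
        res2 = average_linkage(rmsd_matrix(traj2, np.ones(40, dtype=bool)), 2)
        assert canon(res.labels[perm]) == canon(res2.labels)

    def test_population_conservation(self, rng):
        cond = rng.uniform(0.1, 10.0, 28)
        res = average_linkage(DistanceMatrix(condensed=cond,
                                             frame_indices=np.arange(8)), 3)
        assert res.populations.sum() == 8


class TestRepresentatives:
    def test_singleton_cluster(self, csf114):
        top, frame = csf114
        frames = [frame,
                  Frame(coordinates=frame.coordinates + [0, 0, 8.0]),
                  Frame(coordinates=frame.coordinates + [0, 0, 8.1])]
        traj = Trajectory(topology=top, frames=frames)
        m = rmsd_matrix(traj, np.ones(3, dtype=bool))
        res = average_linkage(m, 2)
        reps = representatives(res, traj)
        assert set(reps.values()) <= {0, 1, 2}
        singleton = [lbl for lbl in range(res.n_clusters)
                     if res.populations[lbl] == 1]
        for lbl in singleton:
            assert reps[lbl] == res.frame_indices[res.labels == lbl][0]

    def test_member_equal_to_mean_is_chosen(self, csf114):
        top, frame = csf114
        pep = top.peptide()
        core = np.array(pep.ca_indices(range(5, 13)))
        c0, c1, c2 = (frame.coordinates.copy() for _ in range(3))
        delta = np.zeros_like(frame.coordinates)
        delta[core[2]] = [0, 0, 1.0]
        c0 += delta
        c2 -= delta  # frame 1 equals the mean of 0 and 2 by construction
        traj = Trajectory(topology=top, frames=[Frame(coordinates=c)
                                                for c in (c0, c1, c2)])
        m = rmsd_matrix(traj, np.ones(3, dtype=bool))
        res = average_linkage(m, 1)
        reps = representatives(res, traj)
        assert reps[0] == 1

    def test_representative_minimises_rmsd_to_average(self, csf114, rng):
        top, frame = csf114
        frames = [Frame(coordinates=frame.coordinates
                        + rng.normal(0, 0.4, frame.coordinates.shape))
                  for _ in range(12)]
        traj = Trajectory(topology=top, frames=frames)
        m = rmsd_matrix(traj, np.ones(12, dtype=bool))
        res = average_linkage(m, 2)
        reps = representatives(res, traj)
        pep = top.peptide()
        core = np.array(pep.ca_indices(range(5, 13)))
        for lbl, rep in reps.items():
            mean = res.average_structures[lbl]
            members = res.frame_indices[res.labels == lbl]
            dists = {i: kabsch_superpose(
                traj.frames[i].coordinates[core], mean)[2] for i in members}
            assert dists[rep] == pytest.approx(min(dists.values()), abs=1e-9)


class TestTwoModeFixture:
    def test_full_label_recovery(self, csf114):
        top, frame = csf114
        ref1 = frame.coordinates
        ref2 = ref1.copy()
        ref2[8:14] += np.array([0, 0, 5.0])  # well beyond 0.2 A noise
        traj, labels = make_cluster_fixture(100, [ref1, ref2], 0.2,
                                            [0.6, 0.4], seed=5)
        m = rmsd_matrix(traj, np.ones(100, dtype=bool))
        res = average_linkage(m, 2)
        agreement = max((res.labels == labels).mean(),
                        (res.labels != labels).mean())
        assert agreement == 1.0
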