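"""Cluster matching, Gromov-Wasserstein solver, Procrustes, and the
coordinate-unification strategies."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from maskst.data_model import STSlice
from maskst.local_alignment import (ClusterSubproblem, RigidTransform,
                                    TransformOptConfig, assemble_block_plan,
                                    best_counterparts,
                                    coordinate_replacement_sweep,
                                    coordinate_transformation_optimize,
                                    gw_align_cluster, gw_cost,
                                    match_shared_clusters, transform_coordinates,
                                    weighted_procrustes)


def slice_at(coords, slice_id="s"):
    coords = np.asarray(coords, float)
    n = len(coords)
    return STSlice(slice_id=slice_id, spot_ids=[f"{slice_id}{i}" for i in range(n)],
                   counts=np.ones((n, 2)), coords=coords,
                   gene_ids=["g0", "g1"])


def subproblem(c1, c2, label=0):
    c1, c2 = np.asarray(c1, float), np.asarray(c2, float)
    return ClusterSubproblem(
        label=label, idx1=np.arange(len(c1)), idx2=np.arange(len(c2)),
        D1=cdist(c1, c1), D2=cdist(c2, c2),
        g1=np.full(len(c1), 1 / len(c1)), g2=np.full(len(c2), 1 / len(c2)))


class TestMatchSharedClusters:
    def test_intersection_of_labels(self, rng):
        slices = [slice_at(rng.normal(size=(6, 2)), "a"),
                  slice_at(rng.normal(size=(6, 2)), "b")]
        labels = [np.array([1, 1, 2, 2, 3, 3]), np.array([2, 2, 3, 3, 4, 4])]
        with pytest.warns(RuntimeWarning, match="one slice only"):
            subs = match_shared_clusters(slices, labels)[0]
        assert [s.label for s in subs] == [2, 3]

    def test_identical_labelings_one_per_label(self, rng):
        slices = [slice_at(rng.normal(size=(4, 2)), "a"),
                  slice_at(rng.normal(size=(4, 2)), "b")]
        labels = [np.array([0, 0, 1, 1])] * 2
        subs = match_shared_clusters(slices, labels)[0]
        assert len(subs) == 2

    def test_disjoint_labels_error(self, rng):
        slices = [slice_at(rng.normal(size=(2, 2)), "a"),
                  slice_at(rng.normal(size=(2, 2)), "b")]
        with pytest.raises(ValueError, match="no cluster label"):
            match_shared_clusters(slices, [np.array([0, 0]), np.array([1, 1])])


class TestGW:
    def test_identical_point_sets_zero_cost(self, rng):
        pts = rng.normal(size=(12, 2))
        sub = subproblem(pts, pts)
        Pi = gw_align_cluster(sub)
        assert gw_cost(sub.D1, sub.D2, Pi) <= 1e-6

    def test_singleton_clusters(self):
        sub = subproblem([[0.0, 0.0]], [[5.0, 5.0]])
        assert np.allclose(gw_align_cluster(sub), [[1.0]])

    def test_matches_permutation_enumeration(self, rng):
        """CG solution cost equals the exhaustive minimum over permutation
        couplings on small equal-size clusters."""
        for trial in range(20):
            n = int(rng.integers(2, 7))
            c1 = rng.integers(0, 8, size=(n, 2)).astype(float)
            c2 = rng.integers(0, 8, size=(n, 2)).astype(float)
            sub = subproblem(c1, c2)
            Pi = gw_align_cluster(sub)
            cost = gw_cost(sub.D1, sub.D2, Pi)
            best = min(
                gw_cost(sub.D1, sub.D2, _perm_plan(p, n))
                for p in itertools.permutations(range(n)))
            assert cost <= best + 1e-8

    def test_marginals_conserved(self, rng):
        sub = subproblem(rng.normal(size=(7, 2)), rng.normal(size=(5, 2)))
        Pi = gw_align_cluster(sub)
        assert np.allclose(Pi.sum(axis=1), sub.g1, atol=1e-7)
        assert np.allclose(Pi.sum(axis=0), sub.g2, atol=1e-7)


def _perm_plan(perm, n):
    P = np.zeros((n, n))
    P[np.arange(n), list(perm)] = 1.0 / n
    return P


class TestAssemble:
    def test_block_diagonal_layout(self, rng):
        b1 = np.full((2, 2), 0.25)
        b2 = np.full((3, 3), 1 / 9)
        plan = assemble_block_plan(
            [(0, np.array([0, 1]), np.array([0, 1]), b1),
             (1, np.array([2, 3, 4]), np.array([2, 3, 4]), b2)],
            pair=(0, 1), n1=5, n2=5)
        M, _, _ = plan.sorted_matrix()
        assert M.shape == (5, 5)
        assert np.count_nonzero(M == 0.0) == 12
        full = plan.full_matrix()
        assert np.allclose(full[np.ix_([0, 1], [0, 1])], b1)

    def test_single_block(self):
        b = np.full((2, 2), 0.25)
        plan = assemble_block_plan([(0, np.array([0, 1]), np.array([0, 1]), b)],
                                   pair=(0, 1), n1=2, n2=2)
        assert np.allclose(plan.full_matrix(), b)

    def test_permuted_input_same_full_matrix(self, rng):
        b1 = rng.random((2, 2))
        b2 = rng.random((2, 2))
        blocks = [(0, np.array([0, 2]), np.array([1, 3]), b1),
                  (1, np.array([1, 3]), np.array([0, 2]), b2)]
        M1 = assemble_block_plan(blocks, (0, 1), 4, 4).full_matrix()
        M2 = assemble_block_plan(blocks[::-1], (0, 1), 4, 4).full_matrix()
        assert np.array_equal(M1, M2)

    def test_overlapping_indices_error(self):
        b = np.ones((1, 1))
        with pytest.raises(ValueError, match="overlapping"):
            assemble_block_plan([(0, np.array([0]), np.array([0]), b),
                                 (1, np.array([0]), np.array([1]), b)],
                                (0, 1), 2, 2)


class TestProcrustes:
    def test_identity(self, rng):
        Z = rng.normal(size=(6, 2))
        T = weighted_procrustes(Z, Z, np.eye(6) / 6)
        assert np.allclose(T.R, np.eye(2), atol=1e-10)
        assert np.allclose(T.v, 0.0, atol=1e-10)

    def test_translation_recovery(self, rng):
        Z = rng.normal(size=(5, 2))
        Zp = Z + np.array([3.0, -2.0])
        T = weighted_procrustes(Z, Zp, np.eye(5) / 5)
        assert np.allclose(T.v, [-3.0, 2.0], atol=1e-10)
        assert np.allclose(T.apply(Zp), Z, atol=1e-10)

    def test_rotation_recovery_to_1e8(self, rng):
        Z = rng.normal(size=(8, 2))
        R = RigidTransform.from_angle(np.deg2rad(37.0)).R
        Zp = Z @ R.T
        T = weighted_procrustes(Z, Zp, np.eye(8) / 8)
        assert np.allclose(T.apply(Zp), Z, atol=1e-8)

    def test_beats_random_rigid_transforms(self, rng):
        Z = rng.normal(size=(10, 2))
        Zp = rng.normal(size=(10, 2))
        Pi = rng.random((10, 10))
        Pi /= Pi.sum()
        T = weighted_procrustes(Z, Zp, Pi)

        def objective(R, v):
            moved = Zp @ R.T + v
            return np.sum(Pi * cdist(Z, moved, "sqeuclidean"))

        best = objective(T.R, T.v)
        assert best <= objective(np.eye(2), np.zeros(2)) + 1e-12
        for _ in range(1000):
            Rr = RigidTransform.from_angle(rng.uniform(-np.pi, np.pi)).R
            vr = rng.normal(scale=2.0, size=2)
            assert best <= objective(Rr, vr) + 1e-9

    def test_zero_mass_errors(self, rng):
        with pytest.raises(ValueError, match="mass"):
            weighted_procrustes(np.ones((2, 2)), np.ones((2, 2)),
                                np.zeros((2, 2)))


class TestTransformCoordinates:
    def test_rigid_preserves_distances(self, rng):
        sl = slice_at(rng.normal(size=(7, 2)))
        T = RigidTransform.from_angle(0.83, (2.0, -1.0))
        out = transform_coordinates(sl, T)
        assert np.allclose(cdist(out.coords, out.coords),
                           cdist(sl.coords, sl.coords), atol=1e-10)

    def test_identity_unchanged(self, rng):
        sl = slice_at(rng.normal(size=(4, 2)))
        out = transform_coordinates(sl, RigidTransform.identity())
        assert np.allclose(out.coords, sl.coords)


class TestReplacementSweep:
    def _identity_plan(self, n):
        return assemble_block_plan(
            [(0, np.arange(n), np.arange(n), np.eye(n) / n)], (0, 1), n, n)

    def test_identity_plan_copies_coords(self, rng):
        c = rng.normal(size=(5, 2))
        s1, s2 = slice_at(c, "a"), slice_at(c + 100.0, "b")
        out = coordinate_replacement_sweep([s1, s2], [self._identity_plan(5)])
        assert np.array_equal(out[1].coords, s1.coords)

    def test_three_slice_chain_hand_traced(self):
        s1 = slice_at([[0.0, 0.0], [10.0, 0.0]], "a")
        s2 = slice_at([[50.0, 0.0], [60.0, 0.0]], "b")
        s3 = slice_at([[90.0, 0.0], [99.0, 0.0]], "c")
        # plan 1-2 swaps, plan 2-3 identity: slice-3 spot 0 -> slice-2 spot 0
        # -> slice-1 spot 1, and spot 1 -> spot 0
        swap = assemble_block_plan(
            [(0, np.array([0, 1]), np.array([0, 1]),
              np.array([[0.0, 0.5], [0.5, 0.0]]))], (0, 1), 2, 2)
        ident = assemble_block_plan(
            [(0, np.array([0, 1]), np.array([0, 1]),
              np.array([[0.5, 0.0], [0.0, 0.5]]))], (1, 2), 2, 2)
        out = coordinate_replacement_sweep([s1, s2, s3], [swap, ident])
        assert np.array_equal(out[2].coords, s1.coords[[1, 0]])

    def test_tie_goes_to_lower_index(self):
        plan = assemble_block_plan(
            [(0, np.array([0, 1]), np.array([0]),
              np.array([[0.5], [0.5]]))], (0, 1), 2, 1)
        assert best_counterparts(plan)[0] == 0

    def test_orphan_spot_keeps_coords(self, rng):
        c = rng.normal(size=(2, 2))
        s1, s2 = slice_at(c, "a"), slice_at(c + 5.0, "b")
        plan = assemble_block_plan(
            [(0, np.array([0]), np.array([0]), np.array([[1.0]]))],
            (0, 1), 2, 2)
        with pytest.warns(RuntimeWarning, match="no transport mass"):
            out = coordinate_replacement_sweep([s1, s2], [plan])
        assert np.array_equal(out[1].coords[1], s2.coords[1])

    def test_frame_invariance(self, rng):
        """Pre-rotating slice 1 rotates all output coordinates identically."""
        c = rng.normal(size=(6, 2))
        plan = self._identity_plan(6)
        out = coordinate_replacement_sweep(
            [slice_at(c, "a"), slice_at(c + 3, "b")], [plan])
        T = RigidTransform.from_angle(0.6, (1.0, 2.0))
        out_rot = coordinate_replacement_sweep(
            [slice_at(T.apply(c), "a"), slice_at(c + 3, "b")], [plan])
        assert np.allclose(out_rot[1].coords, T.apply(out[1].coords))


class TestTransformationOptimize:
    def test_coregistered_near_identity(self, rng):
        c = rng.uniform(0, 10, size=(25, 2))
        slices = [slice_at(c, "a"), slice_at(c, "b")]
        links = [(0, i, 1, i) for i in range(25)]
        cfg = TransformOptConfig(popsize=20, maxiter=60, seed=0)
        T = coordinate_transformation_optimize(slices, links, cfg)[1]
        assert np.linalg.norm(T.apply(c) - c, axis=1).max() < 0.3

    def test_recovers_25_degree_rotation(self, rng):
        c = rng.uniform(0, 10, size=(30, 2))
        Trot = RigidTransform.from_angle(np.deg2rad(25.0))
        slices = [slice_at(c, "a"), slice_at(Trot.apply(c), "b")]
        links = [(0, i, 1, i) for i in range(30)]
        cfg = TransformOptConfig(popsize=25, maxiter=120, seed=1)
        T = coordinate_transformation_optimize(slices, links, cfg)[1]
        angle = np.rad2deg(np.arctan2(T.R[1, 0], T.R[0, 0]))
        assert abs(angle - (-25.0)) < 1.0

    def test_seeded_determinism(self, rng):
        c = rng.uniform(0, 5, size=(15, 2))
        slices = [slice_at(c, "a"), slice_at(c + 1.0, "b")]
        links = [(0, i, 1, i) for i in range(15)]
        cfg = TransformOptConfig(popsize=10, maxiter=30, seed=3)
        T1 = coordinate_transformation_optimize(slices, links, cfg)[1]
        T2 = coordinate_transformation_optimize(slices, links, cfg)[1]
        assert np.array_equal(T1.R, T2.R) and np.array_equal(T1.v, T2.v)
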