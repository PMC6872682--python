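"""Kabsch solver, exact closest-point queries, surface RMSD, trimmed ICP."""

import numpy as np
import pytest

from rootaxis.mesh import MeshError, Region, TriangleMesh, extract_region
from rootaxis.registration import (
    DegenerateGeometryError,
    IcpParams,
    MeshProximity,
    RigidTransform,
    closest_point_on_mesh,
    icp_register,
    kabsch,
    principal_axes_prealign,
    surface_rmsd,
)


class TestRigidTransform:
    def test_reflection_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="det"):
            RigidTransform(R, np.zeros(3))

    def test_compose_inverse_is_identity(self, rng):
        T = RigidTransform.from_axis_angle(rng.normal(size=3), 37.0, rng.normal(size=3))
        I = T.compose(T.inverse())
        np.testing.assert_allclose(I.rotation, np.eye(3), atol=1e-12)
        assert np.linalg.norm(I.translation) < 1e-12

    def test_json_round_trip(self):
        T = RigidTransform.from_axis_angle([0, 0, 1], 45.0, [1, 2, 3])
        back = RigidTransform.from_json(T.to_json())
        np.testing.assert_allclose(back.to_matrix(), T.to_matrix(), atol=1e-15)


class TestKabsch:
    def test_identity_on_identical_sets(self, rng):
        pts = rng.normal(size=(20, 3))
        T = kabsch(pts, pts)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        assert np.linalg.norm(T.translation) < 1e-9

    def test_recovers_pure_rotation_exactly(self, rng):
        pts = rng.normal(size=(25, 3))
        true = RigidTransform.from_axis_angle([0, 0, 1], 30.0)
        rec = kabsch(pts, true.apply(pts))
        np.testing.assert_allclose(rec.rotation, true.rotation, atol=1e-9)
        np.testing.assert_allclose(rec.translation, true.translation, atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            kabsch(line, line)

    def test_noisy_fit_beats_random_transforms(self, rng):
        # Monte-Carlo lower bound: the closed-form solution must beat
        # thousands of random rigid transforms on noisy correspondences
        pts = rng.normal(size=(40, 3)) * 5
        true = RigidTransform.from_axis_angle([1, 1, 0], 25.0, [2, -1, 3])
        target = true.apply(pts) + rng.normal(scale=0.05, size=(40, 3))
        fit = kabsch(pts, target)
        best = np.mean(np.sum((fit.apply(pts) - target) ** 2, axis=1))
        from scipy.spatial.transform import Rotation

        Rs = Rotation.random(10_000, random_state=7).as_matrix()
        ts = true.translation + rng.normal(scale=0.5, size=(10_000, 3))
        moved = np.einsum("kij,nj->kni", Rs, pts) + ts[:, None, :]
        rand_res = np.mean(np.sum((moved - target) ** 2, axis=2), axis=1)
        assert best <= rand_res.min() + 1e-12


class TestClosestPoint:
    def test_query_at_vertex_is_zero(self, canine):
        _, mesh, _ = canine
        _, d, _ = MeshProximity(mesh).query(mesh.vertices[100])
        assert d[0] < 1e-12

    def test_foot_of_perpendicular_above_interior(self):
        tri = TriangleMesh(
            np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0]], float), np.array([[0, 1, 2]])
        )
        point, dist, face = closest_point_on_mesh([1.0, 1.0, 2.5], tri)
        np.testing.assert_allclose(point, [1.0, 1.0, 0.0], atol=1e-12)
        assert dist == pytest.approx(2.5, abs=1e-12)
        assert face == 0

    def test_accelerated_query_matches_brute_force(self, canine, rng):
        _, mesh, _ = canine
        prox = MeshProximity(mesh)
        queries = np.vstack(
            [
                rng.uniform(-15, 15, size=(500, 3)) + [0, 0, 12],
                mesh.vertices[rng.choice(mesh.n_vertices, 250)]
                + rng.normal(scale=0.05, size=(250, 3)),
                rng.uniform(-60, 60, size=(250, 3)),
            ]
        )
        _, d_fast, _ = prox.query(queries)
        _, d_brute, _ = prox.query_brute_force(queries)
        np.testing.assert_allclose(d_fast, d_brute, atol=1e-12)


class TestSurfaceRmsd:
    def test_zero_for_points_on_target(self, canine, rng):
        _, mesh, _ = canine
        from rootaxis.registration import sample_surface_points

        pts = sample_surface_points(mesh, 300, seed=4)
        assert surface_rmsd(pts, mesh) < 1e-9

    def test_offset_plane_closed_form(self):
        square = TriangleMesh(
            np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], float),
            np.array([[0, 1, 2], [0, 2, 3]]),
        )
        pts = np.column_stack(
            [np.linspace(2, 8, 20), np.linspace(2, 8, 20), np.full(20, 0.5)]
        )
        assert surface_rmsd(pts, square) == pytest.approx(0.5, abs=1e-12)

    def test_invariant_under_common_rigid_transform(self, canine, rng):
        _, mesh, _ = canine
        pts = mesh.vertices[::7] + rng.normal(scale=0.3, size=mesh.vertices[::7].shape)
        base = surface_rmsd(pts, mesh)
        T = RigidTransform.from_axis_angle([2, -1, 1], 63.0, [5, 4, -3])
        moved = surface_rmsd(T.apply(pts), mesh.transformed(T))
        assert moved == pytest.approx(base, rel=1e-9)

    def test_empty_target_rejected(self):
        empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(MeshError):
            surface_rmsd(np.zeros((5, 3)), empty)


class TestIcp:
    def test_identical_meshes_identity_init(self, canine):
        _, mesh, _ = canine
        res = icp_register(mesh, mesh, params=IcpParams(sample_count=800))
        assert res.converged
        assert res.rmsd < 1e-9
        assert res.transform.rotation_angle_deg() < 1e-6

    def test_known_displacement_recovered(self, canine):
        _, mesh, _ = canine
        true = RigidTransform.from_axis_angle([0.2, 1, 0.1], 10.0, [2.0, 0.0, -1.0])
        moving = mesh.transformed(true.inverse())
        init = principal_axes_prealign(moving, mesh)
        res = icp_register(moving, mesh, init=init, params=IcpParams(sample_count=1000))
        err = res.transform.compose(true.inverse())
        assert err.rotation_angle_deg() < 0.1
        assert np.linalg.norm(err.translation) < 0.01

    def test_rmsd_history_non_increasing(self, canine):
        _, mesh, _ = canine
        true = RigidTransform.from_axis_angle([1, 0, 0], 8.0, [1, 1, 0])
        moving = mesh.transformed(true.inverse())
        params = IcpParams(sample_count=800)
        res = icp_register(moving, mesh, params=params)
        h = np.array(res.rmsd_history)
        assert np.all(np.diff(h) <= params.convergence_tol)

    def test_disjoint_incompatible_meshes_report_large_rmsd(self):
        # a large square cannot lie on a far-away unit triangle: ICP may
        # converge, but the reported RMSD stays large (no silent failure)
        a = TriangleMesh(
            np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], float),
            np.array([[0, 1, 2], [0, 2, 3]]),
        )
        b = TriangleMesh(
            np.array([[100, 0, 0], [101, 0, 0], [100, 1, 0]], float), np.array([[0, 1, 2]])
        )
        res = icp_register(a, b, params=IcpParams(sample_count=100, trim_fraction=0.0))
        assert np.isfinite(res.rmsd)
        assert res.rmsd > 1.0  # visible to the caller, no silent failure

    def test_empty_mesh_rejected(self, canine):
        _, mesh, _ = canine
        empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(MeshError):
            icp_register(empty, mesh)

    def test_transform_recovery_50_seeded_trials(self, canine):
        # rotations up to 20 deg, translations up to 5 mm, noiseless:
        # at least 48/50 recoveries within 0.1 deg / 0.01 mm
        _, mesh, _ = canine
        ok = 0
        for s in range(50):
            rng = np.random.default_rng(1000 + s)
            true = RigidTransform.from_axis_angle(
                rng.normal(size=3), rng.uniform(0, 20), rng.uniform(-5, 5, 3)
            )
            moving = mesh.transformed(true.inverse())
            init = principal_axes_prealign(moving, mesh)
            res = icp_register(moving, mesh, init=init, params=IcpParams(sample_count=800))
            err = res.transform.compose(true.inverse())
            if err.rotation_angle_deg() < 0.1 and np.linalg.norm(err.translation) < 0.01:
                ok += 1
        assert ok >= 48

    def test_crown_only_partial_overlap_alignment(self, canine):
        # trimmed ICP of a crown submesh against the whole tooth must
        # recover the pose within 0.5 deg
        _, mesh, _ = canine
        crown = extract_region(mesh, Region.CROWN)
        true = RigidTransform.from_axis_angle([0.1, 0.3, 1], 12.0, [1.5, -1, 2])
        moving = crown.transformed(true.inverse())
        init = kabsch(moving.vertices[::5], crown.vertices[::5])
        res = icp_register(
            moving, mesh, init=init, params=IcpParams(trim_fraction=0.1, sample_count=800)
        )
        err = res.transform.compose(true.inverse())
        assert err.rotation_angle_deg() < 0.5


class TestIcpParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"max_iterations": 0},
            {"convergence_tol": 0.0},
            {"trim_fraction": 0.6},
            {"correspondence_mode": "nearest_neighbour"},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            IcpParams(**kw)
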