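"""Synthetic tooth/scan/prediction/cast/study generators and their oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import truncnorm

from rootaxis.axis import angle_between_axes, fit_axis
from rootaxis.mesh import Region, extract_region
from rootaxis.registration import RigidTransform, surface_rmsd
from rootaxis.synth import (
    Jaw,
    PredictionParams,
    ScanParams,
    Side,
    ToothParams,
    ToothType,
    _allocate_counts,
    composed_rotation_angle_deg,
    draw_discrepancy_angles,
    generate_cast,
    generate_study,
    generate_tooth,
    simulate_partial_scan,
    simulate_prediction,
)


class TestGenerateTooth:
    def test_zero_curvature_axis_is_construction_axis(self, canine):
        _, _, axis = canine
        np.testing.assert_allclose(axis.direction, [0, 0, 1], atol=1e-12)

    def test_same_seed_gives_identical_meshes(self):
        params = ToothParams.for_type(ToothType.LATERAL_INCISOR, Jaw.MAXILLA)
        a, _ = generate_tooth(params, seed=9)
        b, _ = generate_tooth(params, seed=9)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)
        assert np.array_equal(a.labels, b.labels)

    def test_different_seed_gives_different_surface(self):
        params = ToothParams.for_type(ToothType.LATERAL_INCISOR, Jaw.MAXILLA)
        a, _ = generate_tooth(params, seed=1)
        b, _ = generate_tooth(params, seed=2)
        assert not np.array_equal(a.vertices, b.vertices)

    def test_root_length_along_axis_within_two_percent(self, canine):
        # brute-force projection of root/cervical vertices on the axis:
        # apex to the start of the cervical band spans the root length
        params, mesh, axis = canine
        t = mesh.vertices @ axis.direction
        apex = t[mesh.labels == int(Region.ROOT)].min()
        cervix = t[mesh.labels == int(Region.CERVICAL)].min()
        assert cervix - apex == pytest.approx(params.root_length, rel=0.02)

    def test_labels_cover_all_regions(self, canine):
        _, mesh, _ = canine
        present = set(np.unique(mesh.labels))
        assert {int(Region.CROWN), int(Region.ROOT), int(Region.CERVICAL)} <= present

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ValueError):
            ToothParams(crown_height=0.0)

    def test_curved_root_keeps_reported_axis_straight(self):
        params = ToothParams.for_type(
            ToothType.CANINE, Jaw.MANDIBLE, root_curvature_deg=10.0
        )
        mesh, axis = generate_tooth(params, seed=3)
        np.testing.assert_allclose(axis.direction, [0, 0, 1], atol=1e-12)
        # the bent apex deviates from the axis on the bend side
        apex = mesh.vertices[np.argmin(mesh.vertices[:, 2])]
        assert apex[1] > 0.5


class TestSimulatePartialScan:
    def _still(self, seed=0, **kw):
        return ScanParams(
            noise_sd=kw.pop("noise_sd", 0.0),
            pose_rotation_max_deg=0.0,
            pose_translation_max_mm=0.0,
            seed=seed,
            **kw,
        )

    def test_noiseless_identity_pose_is_strict_submesh(self, canine):
        _, mesh, _ = canine
        scan, pose = simulate_partial_scan(mesh, "crown_side", self._still())
        assert pose.rotation_angle_deg() < 1e-12
        tooth_set = {tuple(v) for v in np.round(mesh.vertices, 9)}
        scan_set = {tuple(v) for v in np.round(scan.vertices, 9)}
        assert scan_set < tooth_set

    def test_two_stages_cover_every_vertex(self, canine):
        _, mesh, _ = canine
        a, _ = simulate_partial_scan(mesh, "crown_side", self._still())
        b, _ = simulate_partial_scan(mesh, "root_side", self._still())
        tooth_set = {tuple(v) for v in np.round(mesh.vertices, 9)}
        union = {tuple(v) for v in np.round(a.vertices, 9)} | {
            tuple(v) for v in np.round(b.vertices, 9)
        }
        assert union == tooth_set

    def test_no_overlap_clip_fraction_rejected(self, canine):
        _, mesh, _ = canine
        with pytest.raises(ValueError, match="overlap"):
            simulate_partial_scan(mesh, "crown_side", self._still(clip_fraction=0.5))

    def test_noise_magnitude_matches_half_normal_mean(self, canine):
        # |N(0, sd)| has mean sd * sqrt(2/pi); check the Monte-Carlo
        # average displacement over 20 seeds against that expectation
        _, mesh, _ = canine
        sd = 0.01
        clean, _ = simulate_partial_scan(mesh, "crown_side", self._still())
        mags = []
        for seed in range(20):
            noisy, _ = simulate_partial_scan(
                mesh, "crown_side", self._still(seed=seed, noise_sd=sd)
            )
            mags.append(np.linalg.norm(noisy.vertices - clean.vertices, axis=1).mean())
        expected = sd * np.sqrt(2.0 / np.pi)
        assert np.mean(mags) == pytest.approx(expected, rel=0.02)

    def test_pose_is_returned_and_applied(self, canine):
        _, mesh, _ = canine
        params = ScanParams(noise_sd=0.0, seed=5)
        scan, pose = simulate_partial_scan(mesh, "root_side", params)
        # undoing the pose puts the scan back onto the tooth surface
        back = scan.transformed(pose.inverse())
        assert surface_rmsd(back.vertices, mesh) < 1e-9


class TestSimulatePrediction:
    def test_zero_angles_is_identity(self, canine):
        _, mesh, _ = canine
        pred, gt = simulate_prediction(mesh, PredictionParams(0.0, 0.0))
        np.testing.assert_array_equal(pred.vertices, mesh.vertices)
        assert gt.injected_angle_deg == 0.0

    def test_single_axis_rotation_angle(self, canine):
        _, mesh, _ = canine
        _, gt = simulate_prediction(mesh, PredictionParams(tip_deg=10.0))
        assert gt.injected_angle_deg == pytest.approx(10.0, abs=1e-9)

    def test_composed_angle_matches_quaternion_oracle(self):
        for tip, torque in [(10, 10), (25, -12), (-5, 30), (3, 4)]:
            r = Rotation.from_euler("x", torque, degrees=True) * Rotation.from_euler(
                "y", tip, degrees=True
            )
            expected = np.degrees(r.magnitude())
            assert composed_rotation_angle_deg(tip, torque) == pytest.approx(
                expected, abs=1e-9
            )

    def test_crown_unchanged_root_rotated_about_cervical_centroid(self, canine):
        _, mesh, _ = canine
        pred, gt = simulate_prediction(mesh, PredictionParams(tip_deg=15.0))
        crown_mask = mesh.labels != int(Region.ROOT)
        np.testing.assert_array_equal(
            pred.vertices[crown_mask], mesh.vertices[crown_mask]
        )
        pivot = mesh.vertices[mesh.labels == int(Region.CERVICAL)].mean(axis=0)
        T = gt.transforms[0]
        np.testing.assert_allclose(T.apply(pivot), pivot, atol=1e-9)
        # the predicted root axis is the rotated true axis
        pred_root = extract_region(pred, Region.ROOT)
        fitted = fit_axis(pred_root.vertices)
        expected = gt.true_axis.transformed(T)
        assert angle_between_axes(fitted, expected) < 0.05


class TestGenerateCast:
    def test_single_tooth_cast_has_no_root(self, canine):
        _, mesh, _ = canine
        cast, placements = generate_cast([mesh])
        assert not np.any(cast.labels == int(Region.ROOT))
        assert len(placements) == 1

    def test_n_teeth_recoverable_crowns(self):
        teeth = [
            generate_tooth(ToothParams.for_type(ToothType.CENTRAL_INCISOR, Jaw.MANDIBLE), seed=s)[0]
            for s in range(3)
        ]
        cast, placements = generate_cast(teeth)
        assert set(np.unique(cast.tooth_ids)) == {0, 1, 2}

    def test_cast_crown_matches_placed_tooth_crown_exactly(self, canine):
        _, mesh, _ = canine
        cast, placements = generate_cast([mesh])
        keep = (mesh.labels == int(Region.CROWN)) | (mesh.labels == int(Region.CERVICAL))
        crown = mesh.submesh_from_vertex_mask(keep).transformed(placements[0])
        np.testing.assert_allclose(
            np.sort(cast.vertices, axis=0), np.sort(crown.vertices, axis=0), atol=1e-12
        )

    def test_overlapping_crowns_warn_not_error(self, canine):
        _, mesh, _ = canine
        with pytest.warns(UserWarning, match="overlap"):
            generate_cast([mesh, mesh.copy()], arch_spacing=-5.0)


class TestGenerateStudy:
    def test_55_teeth_yield_55_ground_truth_records(self):
        bundle = generate_study(n_teeth=55, seed=3)
        assert len(bundle.ground_truth) == 55
        assert len(bundle.teeth) == 55
        assert bundle.ground_truth.tooth_id.is_unique

    def test_default_composition_matches_sample_distribution(self):
        counts = {(j, t): c for j, t, c in _allocate_counts(55)}
        assert counts[(Jaw.MAXILLA, ToothType.CENTRAL_INCISOR)] == 3
        assert counts[(Jaw.MAXILLA, ToothType.LATERAL_INCISOR)] == 3
        assert counts[(Jaw.MAXILLA, ToothType.CANINE)] == 4
        assert counts[(Jaw.MANDIBLE, ToothType.CENTRAL_INCISOR)] == 14
        assert counts[(Jaw.MANDIBLE, ToothType.LATERAL_INCISOR)] == 13
        assert counts[(Jaw.MANDIBLE, ToothType.CANINE)] == 18

    def test_zero_sd_gives_constant_angles(self):
        bundle = generate_study(n_teeth=4, discrepancy_mean=8.0, discrepancy_sd=0.0, seed=1)
        np.testing.assert_allclose(bundle.ground_truth.injected_angle_deg, 8.0, atol=1e-9)

    def test_injected_angle_equals_composed_rotation_angle(self):
        bundle = generate_study(n_teeth=5, seed=8)
        for _, row in bundle.ground_truth.iterrows():
            assert composed_rotation_angle_deg(
                row.tip_deg, row.torque_deg
            ) == pytest.approx(row.injected_angle_deg, abs=1e-9)

    def test_truncated_normal_draw_moments(self):
        # sample mean over n=500 within 3 SE of the truncated-normal mean
        mean, sd, n = 9.7, 7.0, 500
        draws = draw_discrepancy_angles(n, mean, sd, rng=42)
        a, b = (0 - mean) / sd, (89 - mean) / sd
        mu = truncnorm.mean(a, b, loc=mean, scale=sd)
        se = truncnorm.std(a, b, loc=mean, scale=sd) / np.sqrt(n)
        assert abs(draws.mean() - mu) < 3 * se

    def test_explicit_angles_are_honoured(self):
        angles = np.array([2.0, 10.0, 38.0])
        bundle = generate_study(n_teeth=3, seed=5, angles=angles)
        got = np.sort(bundle.ground_truth.injected_angle_deg.to_numpy())
        np.testing.assert_allclose(got, np.sort(angles), atol=1e-9)

    def test_reproducible_per_seed(self):
        a = generate_study(n_teeth=3, seed=17)
        b = generate_study(n_teeth=3, seed=17)
        assert a.ground_truth.equals(b.ground_truth)
        assert np.array_equal(a.teeth[0].mesh.vertices, b.teeth[0].mesh.vertices)
        assert np.array_equal(a.teeth[2].scan_b.vertices, b.teeth[2].scan_b.vertices)

    def test_fixture_round_trip(self, tmp_path):
        from rootaxis.mesh import read_mesh

        bundle = generate_study(n_teeth=2, seed=4)
        bundle.write_fixture(tmp_path)
        back = read_mesh(tmp_path / "tooth_00_full.ply")
        np.testing.assert_allclose(back.vertices, bundle.teeth[0].mesh.vertices, atol=1e-12)
        np.testing.assert_array_equal(back.labels, bundle.teeth[0].mesh.labels)
        assert (tmp_path / "ground_truth.csv").exists()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            generate_study(n_teeth=0)
        with pytest.raises(ValueError):
            generate_study(n_teeth=3, discrepancy_mean=-1.0)
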