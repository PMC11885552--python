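"""Mirroring, centroid size, thin-plate-spline estimation, GPA properties."""
import numpy as np
import pytest

from phylomorph.geometry import (
    GeneralizedProcrustes,
    GeometryError,
    ThinPlateSpline2D,
    centroid_size,
    estimate_missing_tps,
    gpa_align,
    mirror_config,
    procrustes_distance,
    total_bending_energy,
)
from phylomorph.io import LandmarkSet


def _random_similarity(rng, config):
    theta = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    s = float(np.exp(rng.uniform(-1, 1)))
    t = rng.uniform(-10, 10, size=2)
    return s * config @ R.T + t


class TestMirrorAndSize:
    def test_mirror_negates_stated_coordinate(self):
        cfg = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_allclose(mirror_config(cfg, "x"), [[-1, 2], [-3, 4]])
        np.testing.assert_allclose(mirror_config(cfg, "y"), [[1, -2], [3, -4]])

    def test_double_mirror_is_identity(self, rng):
        cfg = rng.normal(size=(7, 2))
        np.testing.assert_allclose(mirror_config(mirror_config(cfg, "x"), "x"), cfg)

    def test_symmetric_config_aligns_with_its_mirror(self):
        # every landmark on the symmetry axis: the mirror is the shape itself
        cfg = np.array([[0, 1.0], [0, -1.0], [0, 0.5], [0, -0.3]])
        assert procrustes_distance(cfg, mirror_config(cfg, "x")) < 1e-10

    def test_unit_square_centroid_size(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        # brute-force formula: 4 corners each 0.5²+0.5² from the centre
        expected = np.sqrt(4 * (0.5**2 + 0.5**2))
        assert centroid_size(square) == pytest.approx(expected)
        assert expected == pytest.approx(np.sqrt(2))

    def test_scale_equivariance(self, rng):
        cfg = rng.normal(size=(9, 2))
        assert centroid_size(3 * cfg) == pytest.approx(3 * centroid_size(cfg))

    def test_degenerate_configuration_errors(self):
        with pytest.raises(GeometryError, match="degenerate"):
            centroid_size(np.ones((4, 2)))


class TestThinPlateSpline:
    def test_interpolates_its_own_landmarks(self, rng):
        src = rng.normal(size=(8, 2))
        dst = rng.normal(size=(8, 2))
        tps = ThinPlateSpline2D(src, dst)
        np.testing.assert_allclose(tps(src), dst, atol=1e-9)

    def test_deleted_points_restored_exactly_for_identical_specimen(self, rng):
        ref = rng.normal(size=(10, 2))
        coords = np.stack([ref, ref.copy()])
        missing = np.zeros((2, 10), dtype=bool)
        missing[1, [2, 7]] = True
        coords[1, [2, 7]] = np.nan
        lm = LandmarkSet(["a", "b"], coords, (), missing)
        out = estimate_missing_tps(lm, reference=ref)
        np.testing.assert_allclose(out.coords[1], ref, atol=1e-8)
        assert not out.missing.any()

    def test_affine_image_restored_exactly(self, rng):
        # the TPS affine part reproduces any affine map with zero bending
        ref = rng.normal(size=(12, 2))
        A = np.array([[1.3, 0.4], [-0.2, 0.8]])
        b = np.array([2.0, -1.0])
        warped = ref @ A.T + b
        coords = np.stack([ref, warped])
        missing = np.zeros((2, 12), dtype=bool)
        missing[1, [0, 5, 11]] = True
        coords[1, [0, 5, 11]] = np.nan
        lm = LandmarkSet(["ref", "aff"], coords, (), missing)
        out = estimate_missing_tps(lm, reference=ref)
        np.testing.assert_allclose(out.coords[1], ref @ A.T + b, atol=1e-8)

    def test_too_few_shared_points_errors(self, rng):
        ref = rng.normal(size=(4, 2))
        coords = np.stack([ref, ref.copy()])
        missing = np.zeros((2, 4), dtype=bool)
        missing[1, [0, 1]] = True
        coords[1, [0, 1]] = np.nan
        lm = LandmarkSet(["a", "b"], coords, (), missing)
        with pytest.raises(GeometryError, match="b"):
            estimate_missing_tps(lm, reference=ref)

    def test_fixture_estimated_taxa_completed(self, fixture_data):
        landmarks, _, _ = fixture_data
        assert set(
            sid for sid, row in zip(landmarks.specimen_ids, landmarks.missing) if row.any()
        ) == {"Llukalkan", "Abelisaurus"}
        out = estimate_missing_tps(landmarks)
        assert not out.missing.any()
        assert np.isfinite(out.coords).all()


class TestGpa:
    def test_identical_triangles_have_zero_procrustes_distance(self, rng):
        tri = np.array([[0, 0], [2, 0], [0.6, 1.4]])
        coords = np.stack([_random_similarity(rng, tri) for _ in range(4)])
        lm = LandmarkSet([f"s{i}" for i in range(4)], coords)
        shapes = gpa_align(lm, slide_semilandmarks=False)
        for i in range(1, 4):
            assert procrustes_distance(shapes.aligned[0], shapes.aligned[i]) < 1e-10

    def test_alignment_invariant_under_similarity_transforms(self, rng):
        mean = rng.normal(size=(11, 2))
        base = mean[None] + 0.15 * rng.normal(size=(10, 11, 2))
        lm1 = LandmarkSet([f"s{i}" for i in range(10)], base.copy())
        coords2 = np.stack([_random_similarity(rng, c) for c in base])
        lm2 = LandmarkSet([f"s{i}" for i in range(10)], coords2)
        a = gpa_align(lm1, slide_semilandmarks=False).aligned
        b = gpa_align(lm2, slide_semilandmarks=False).aligned
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_pairwise_distances_reproduced_after_transforms(self, rng):
        mean = rng.normal(size=(8, 2))
        base = mean[None] + 0.2 * rng.normal(size=(10, 8, 2))
        lm1 = LandmarkSet([f"s{i}" for i in range(10)], base.copy())
        coords2 = np.stack([_random_similarity(rng, c) for c in base])
        lm2 = LandmarkSet([f"s{i}" for i in range(10)], coords2)
        s1 = gpa_align(lm1, slide_semilandmarks=False)
        s2 = gpa_align(lm2, slide_semilandmarks=False)
        # oracle: brute-force ordinary Procrustes distances between pairs
        for i in range(0, 10, 3):
            for j in range(i + 1, 10, 3):
                d1 = procrustes_distance(s1.aligned[i], s1.aligned[j])
                d2 = procrustes_distance(s2.aligned[i], s2.aligned[j])
                assert d1 == pytest.approx(d2, abs=1e-8)

    def test_aligned_shapes_are_centred_unit_size(self, fixture_data):
        landmarks, _, _ = fixture_data
        est = GeneralizedProcrustes(project_tangent=False).fit(
            estimate_missing_tps(landmarks)
        )
        for cfg in est.shape_data_.aligned:
            np.testing.assert_allclose(cfg.mean(0), 0, atol=1e-9)
            assert np.sqrt((cfg**2).sum()) == pytest.approx(1.0, abs=1e-9)

    def test_tangent_projection_keeps_shapes_near_the_sphere(self, fixture_shapes):
        # orthogonal projection can only lengthen the chord: sizes sit just
        # above 1, by a second-order amount in the shape dispersion
        for cfg in fixture_shapes.aligned:
            np.testing.assert_allclose(cfg.mean(0), 0, atol=1e-9)
            assert 1.0 - 1e-9 <= np.sqrt((cfg**2).sum()) < 1.05

    def test_procrustes_ss_monotone_descent_without_sliding(self, rng):
        mean = rng.normal(size=(9, 2))
        base = mean[None] + 0.3 * rng.normal(size=(12, 9, 2))
        lm = LandmarkSet([f"s{i}" for i in range(12)], base)
        shapes = gpa_align(lm, slide_semilandmarks=False)
        ss = np.array(shapes.procrustes_ss_path)
        assert (np.diff(ss) <= 1e-10).all()

    def test_sliding_reduces_bending_energy(self, fixture_data):
        landmarks, _, _ = fixture_data
        completed = estimate_missing_tps(landmarks)
        slid = gpa_align(completed, slide_semilandmarks=True)
        unslid = gpa_align(completed, slide_semilandmarks=False)
        be_slid = total_bending_energy(slid.aligned, slid.consensus)
        be_unslid = total_bending_energy(unslid.aligned, unslid.consensus)
        assert be_slid <= be_unslid + 1e-12

    def test_sliding_procrustes_criterion_reduces_ss(self, fixture_data):
        landmarks, _, _ = fixture_data
        completed = estimate_missing_tps(landmarks)
        slid = gpa_align(completed, slide_criterion="procrustes")
        unslid = gpa_align(completed, slide_semilandmarks=False)
        ss = lambda s: float(((s.aligned - s.consensus) ** 2).sum())
        assert ss(slid) <= ss(unslid) + 1e-12

    def test_missing_landmarks_rejected(self, fixture_data):
        landmarks, _, _ = fixture_data
        with pytest.raises(GeometryError, match="estimate_missing_tps"):
            gpa_align(landmarks)

    def test_estimator_interface(self, fixture_data):
        landmarks, _, _ = fixture_data
        est = GeneralizedProcrustes(slide_semilandmarks=False)
        est.fit(estimate_missing_tps(landmarks))
        assert est.consensus_.shape == (19, 2)
        assert est.centroid_sizes_.shape == (17,)
        params = est.get_params()
        assert params["slide_criterion"] == "bending_energy"
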