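import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from fus3d import (DistanceSet, SimilarityTransform, cloud_to_mesh_distances,
                   closest_points_on_mesh, compute_rms,
                   estimate_similarity_from_pairs, icp_refine,
                   scale_from_landmark, summarize_alignment)


def random_similarity(seed, s=1.07):
    rng = np.random.default_rng(seed)
    return SimilarityTransform(
        s=s, Rm=Rotation.random(random_state=seed).as_matrix(),
        t=rng.uniform(-5, 5, 3))


class TestSimilarityTransform:
    def test_apply_then_invert_roundtrip(self):
        T = random_similarity(0)
        pts = np.random.default_rng(1).normal(size=(20, 3))
        assert np.allclose(T.inverse().apply(T.apply(pts)), pts, atol=1e-9)

    def test_matrix_agrees_with_apply(self):
        T = random_similarity(2)
        p = np.array([1.0, -2.0, 3.0])
        homog = T.matrix @ np.append(p, 1.0)
        assert np.allclose(homog[:3], T.apply(p), atol=1e-12)

    def test_compose(self):
        A, B = random_similarity(3), random_similarity(4, s=0.8)
        p = np.array([0.5, 1.5, -0.5])
        assert np.allclose(A.compose(B).apply(p), A.apply(B.apply(p)), atol=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            SimilarityTransform(s=-1.0)
        with pytest.raises(ValueError):
            SimilarityTransform(Rm=np.diag([1.0, 1.0, -1.0]))  # improper


class TestEstimateSimilarity:
    def test_exact_recovery_noiseless(self):
        T = random_similarity(5)
        src = np.random.default_rng(6).normal(size=(8, 3))
        est = estimate_similarity_from_pairs(src, T.apply(src))
        assert est.s == pytest.approx(T.s, abs=1e-9)
        assert np.allclose(est.Rm, T.Rm, atol=1e-9)
        assert np.allclose(est.t, T.t, atol=1e-9)

    def test_identical_pairs_give_identity(self):
        src = np.random.default_rng(7).normal(size=(5, 3))
        est = estimate_similarity_from_pairs(src, src)
        assert est.s == pytest.approx(1.0)
        assert np.allclose(est.Rm, np.eye(3), atol=1e-9)
        assert np.allclose(est.t, 0.0, atol=1e-9)

    def test_scale_recovery_under_small_noise(self):
        """Monte-Carlo with known ground truth: sub-0.1% scale error."""
        T = random_similarity(8)
        rng = np.random.default_rng(9)
        src = rng.uniform(-10, 10, (10, 3))
        dst = T.apply(src) + rng.normal(0, 0.01, src.shape)
        est = estimate_similarity_from_pairs(src, dst)
        assert abs(est.s - T.s) / T.s < 1e-3

    def test_residual_matches_reported_application(self):
        rng = np.random.default_rng(10)
        src = rng.normal(size=(12, 3))
        dst = rng.normal(size=(12, 3))
        est = estimate_similarity_from_pairs(src, dst)
        # least squares: residual must not decrease under small perturbations
        base = np.sum((est.apply(src) - dst) ** 2)
        for eps in (1e-3, -1e-3):
            perturbed = SimilarityTransform(s=est.s * (1 + eps), Rm=est.Rm,
                                            t=est.t)
            assert np.sum((perturbed.apply(src) - dst) ** 2) >= base

    def test_too_few_or_degenerate_pairs(self):
        with pytest.raises(ValueError):
            estimate_similarity_from_pairs(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            estimate_similarity_from_pairs(line, line + 1.0)


class TestDistances:
    BIG_TRI = trimesh.Trimesh(vertices=[[-100, -100, 0], [100, -100, 0], [0, 100, 0]],
                              faces=[[0, 1, 2]])

    def test_point_above_plane(self):
        ds = cloud_to_mesh_distances(np.array([[0.0, 0.0, 1.0]]), self.BIG_TRI,
                                     signed=False)
        assert ds.d[0] == pytest.approx(1.0, abs=1e-12)

    def test_point_on_surface_is_zero(self):
        ds = cloud_to_mesh_distances(np.array([[0.0, 0.0, 0.0]]), self.BIG_TRI,
                                     signed=False)
        assert ds.d[0] == pytest.approx(0.0, abs=1e-12)

    def test_signed_reflection_flips_sign(self):
        ds = cloud_to_mesh_distances(
            np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]), self.BIG_TRI,
            signed=True)
        assert ds.d[0] * ds.d[1] == pytest.approx(-1.0, abs=1e-9)
        assert abs(ds.d[0]) == pytest.approx(1.0)

    def test_exactness_against_dense_sampling_oracle(self):
        """Exact distances agree with a dense surface-sampling oracle up to
        the oracle's own resolution, and never exceed it."""
        box = trimesh.creation.box(extents=[6, 4, 2])
        rng = np.random.default_rng(11)
        pts = rng.uniform(-6, 6, (80, 3))
        _, dist, _ = closest_points_on_mesh(pts, box)
        u = np.linspace(0, 1, 80)
        bary = np.array([(a, b, 1 - a - b) for a in u for b in u if a + b <= 1])
        samples = np.einsum("kb,fbj->kfj", bary, box.triangles).reshape(-1, 3)
        d_oracle, _ = cKDTree(samples).query(pts)
        assert (dist <= d_oracle + 1e-12).all()
        assert np.abs(dist - d_oracle).max() < 0.08  # oracle grid resolution

    def test_empty_mesh_raises(self):
        with pytest.raises((ValueError, AttributeError)):
            cloud_to_mesh_distances(np.zeros((1, 3)), trimesh.Trimesh())


class TestStatistics:
    def test_rms_hand_arithmetic(self):
        assert compute_rms(DistanceSet(d=[3.0, 4.0])) == pytest.approx(
            np.sqrt(12.5))
        assert compute_rms(DistanceSet(d=[0.0, 0.0])) == 0.0
        assert compute_rms(DistanceSet(d=[-2.5])) == pytest.approx(2.5)

    def test_rms_permutation_invariant_and_squares(self):
        rng = np.random.default_rng(12)
        d = rng.normal(size=50)
        a = compute_rms(DistanceSet(d=d))
        b = compute_rms(DistanceSet(d=rng.permutation(d)))
        assert a == pytest.approx(b, abs=1e-12)
        assert a ** 2 == pytest.approx(np.mean(d ** 2), abs=1e-12)

    def test_summary_of_symmetric_pair(self):
        rep = summarize_alignment(DistanceSet(d=[-1.0, 1.0]))
        assert rep.mean_distance == 0.0
        assert rep.std_deviation == pytest.approx(np.sqrt(2))
        assert rep.rms == pytest.approx(1.0)

    def test_summary_of_constant_distances(self):
        rep = summarize_alignment(DistanceSet(d=[0.5, 0.5, 0.5]))
        assert rep.mean_distance == pytest.approx(0.5)
        assert rep.std_deviation == 0.0
        assert rep.rms == pytest.approx(0.5)

    def test_gaussian_coverage_fractions(self):
        """~95% of Gaussian distances fall within ±2σ and ~99% within ±3σ."""
        rng = np.random.default_rng(13)
        rep = summarize_alignment(DistanceSet(d=rng.normal(0, 0.35, 100_000)))
        assert rep.frac_within_2std == pytest.approx(0.9545, abs=0.01)
        assert rep.frac_within_3std == pytest.approx(0.9973, abs=0.005)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            compute_rms(DistanceSet(d=[]))
        with pytest.raises(ValueError):
            summarize_alignment(DistanceSet(d=[1.0]))


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40))
def test_rms_permutation_invariance_and_square_identity(d):
    """RMS is symmetric in its arguments and rms² = mean(d²) exactly."""
    arr = np.array(d)
    r = compute_rms(DistanceSet(d=arr))
    assert r >= 0
    assert r ** 2 == pytest.approx(float(np.mean(arr ** 2)), rel=1e-9, abs=1e-12)
    assert compute_rms(DistanceSet(d=arr[::-1])) == pytest.approx(r, abs=1e-12)


class TestScaleFromLandmark:
    def test_values(self):
        assert scale_from_landmark(15.0, 15.0) == 1.0
        assert scale_from_landmark(13.939, 15.0) == pytest.approx(1.0761, abs=1e-4)
        assert scale_from_landmark(30.0, 15.0) == 0.5

    def test_non_positive_raises(self):
        with pytest.raises(ValueError):
            scale_from_landmark(0.0, 15.0)
        with pytest.raises(ValueError):
            scale_from_landmark(10.0, -1.0)


@pytest.fixture(scope="module")
def box_cloud():
    box = trimesh.creation.box(extents=[10, 8, 6])
    pts, _ = trimesh.sample.sample_surface(box, 600, seed=14)
    return box, np.asarray(pts)


class TestICP:
    def test_already_aligned_is_fixed_point(self, box_cloud):
        box, pts = box_cloud
        tr, rep = icp_refine(pts, box, tol=1e-9)
        assert rep.rms == pytest.approx(0.0, abs=1e-9)
        assert tr.s == pytest.approx(1.0, abs=1e-9)
        assert rep.iterations <= 2  # one effective iteration + stop check

    def test_recovers_similarity_with_noise(self, box_cloud):
        box, pts = box_cloud
        rng = np.random.default_rng(15)
        true = random_similarity(16, s=1.07)
        cloud = true.inverse().apply(pts) + rng.normal(0, 0.05, pts.shape)
        lm_t = pts[:3]
        init = estimate_similarity_from_pairs(true.inverse().apply(lm_t), lm_t)
        tr, rep = icp_refine(cloud, box, init=init, with_scale=True)
        assert abs(tr.s - true.s) / true.s < 0.01
        assert rep.converged

    def test_rms_history_non_increasing(self, box_cloud):
        box, pts = box_cloud
        true = random_similarity(17, s=0.95)
        cloud = true.inverse().apply(pts)
        init = estimate_similarity_from_pairs(cloud[:4], pts[:4])
        _, rep = icp_refine(cloud, box, init=init)
        hist = np.array(rep.rms_history)
        assert (np.diff(hist) <= 1e-9).all()

    def test_report_reproducible_from_returned_transform(self, box_cloud):
        box, pts = box_cloud
        rng = np.random.default_rng(18)
        cloud = pts + rng.normal(0, 0.1, pts.shape)
        tr, rep = icp_refine(cloud, box, signed=True)
        ds = cloud_to_mesh_distances(tr.apply(cloud), box, signed=True)
        again = summarize_alignment(ds, transform=tr)
        assert rep.rms == pytest.approx(again.rms, abs=1e-9)
        assert rep.mean_distance == pytest.approx(again.mean_distance, abs=1e-9)

    def test_without_scale_leaves_larger_residual(self, box_cloud):
        box, pts = box_cloud
        cloud = pts / 1.07  # scale-distorted input
        _, rep_scaled = icp_refine(cloud, box, with_scale=True)
        _, rep_rigid = icp_refine(cloud, box, with_scale=False)
        assert rep_rigid.rms > rep_scaled.rms

    def test_point_cloud_reference(self, box_cloud):
        box, pts = box_cloud
        tr, rep = icp_refine(pts + 0.5, pts, with_scale=False)
        assert rep.rms < 1e-6
        assert np.allclose(tr.t, -0.5, atol=1e-6)

    def test_non_convergence_flagged_not_raised(self, box_cloud):
        box, pts = box_cloud
        cloud = pts / 1.07 + 0.3
        _, rep = icp_refine(cloud, box, max_iter=1)
        assert rep.converged is False

    def test_empty_inputs_raise(self, box_cloud):
        box, _ = box_cloud
        with pytest.raises(ValueError):
            icp_refine(np.empty((0, 3)), box)
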