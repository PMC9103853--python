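import numpy as np
import pytest

from fus3d import (Arch, Box, CalibrationMatrix, NoiseSpec, PhantomSpec, Pose,
                   SweepSpec, cloud_to_mesh_distances, default_phantom_spec,
                   make_phantom_mesh, make_sweep_poses, pair_frames_with_poses,
                   phantom_components, reconstruct_cloud, render_frame)


class TestPhantomMesh:
    def test_single_box_mesh(self):
        spec = PhantomSpec(primitives=[Box(extents=(10, 10, 5))],
                           include_landmark=False)
        mesh = make_phantom_mesh(spec)
        assert len(mesh.faces) == 12
        assert mesh.area == pytest.approx(400.0)  # 2(ab+bc+ca)

    def test_default_components_watertight_and_outward(self):
        parts = phantom_components(default_phantom_spec())
        assert set(parts) >= {"arch_0", "box_1", "landmark"}
        for mesh in parts.values():
            assert mesh.is_watertight
            assert mesh.volume > 0  # outward normals: positive signed volume

    def test_landmark_bar_length(self):
        parts = phantom_components(default_phantom_spec())
        lm = parts["landmark"]
        extent = lm.vertices[:, 0].max() - lm.vertices[:, 0].min()
        assert extent == pytest.approx(15.0)

    def test_degenerate_primitive_raises(self):
        with pytest.raises(ValueError):
            make_phantom_mesh(PhantomSpec(primitives=[Box(extents=(0, 1, 1))],
                                          include_landmark=False))
        with pytest.raises(ValueError):
            Arch(inner_radius=5, outer_radius=4, height=1).build()
        with pytest.raises(ValueError):
            make_phantom_mesh(PhantomSpec(primitives=[], include_landmark=False))


class TestSweep:
    def test_zero_jitter_poses_on_linear_path(self):
        spec = SweepSpec(start=(0, 0, 10), end=(9, 0, 10), n_frames=10,
                         jitter_pos_sigma=0.0, jitter_rot_sigma=0.0)
        poses = make_sweep_poses(spec)
        xs = np.array([p.M[0, 3] for p in poses])
        assert np.allclose(xs, np.arange(10.0))
        assert np.allclose(np.diff(xs), 1.0)

    def test_timestamp_span_at_frame_rate(self):
        poses = make_sweep_poses(SweepSpec(n_frames=500, frame_rate=33.0))
        span = poses[-1].timestamp - poses[0].timestamp
        assert span == pytest.approx(499 / 33.0)  # ~15.12 s

    def test_same_seed_reproduces_poses(self):
        a = make_sweep_poses(SweepSpec(n_frames=20, seed=3))
        b = make_sweep_poses(SweepSpec(n_frames=20, seed=3))
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.M, pb.M)

    def test_out_and_back_returns_to_start(self):
        spec = SweepSpec(start=(0, 0, 10), end=(10, 0, 10), n_frames=11,
                         jitter_pos_sigma=0.0, jitter_rot_sigma=0.0,
                         out_and_back=True)
        poses = make_sweep_poses(spec)
        assert poses[0].M[0, 3] == pytest.approx(0.0)
        assert poses[5].M[0, 3] == pytest.approx(10.0)
        assert poses[-1].M[0, 3] == pytest.approx(0.0)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            SweepSpec(n_frames=0)
        with pytest.raises(ValueError):
            SweepSpec(jitter_pos_sigma=-1.0)


@pytest.fixture(scope="module")
def flat_scene():
    """A box with a flat top at z = 2 and a probe looking straight down."""
    spec = PhantomSpec(primitives=[Box(extents=(20, 8, 4))], include_landmark=False)
    mesh = make_phantom_mesh(spec)
    C = CalibrationMatrix.from_pixel_spacing(0.1, center_u=50)
    M = np.eye(4)
    M[:3, :3] = np.array([[0, 0, -1], [1, 0, 0], [0, -1, 0]], dtype=float)
    M[:3, 3] = (0.0, 0.0, 8.0)
    return mesh, Pose(timestamp=0.0, M=M), C


class TestRenderFrame:
    def test_flat_face_gives_constant_row_envelope(self, flat_scene):
        mesh, pose, C = flat_scene
        frame, gt = render_frame(mesh, pose, C, size=(100, 100),
                                 noise=NoiseSpec(speckle_sigma=0.0))
        rows = {y for _, y in gt.pixel_list}
        assert rows == {60}  # (8 - 2) mm depth at 0.1 mm/px
        xs = [x for x, _ in gt.pixel_list]
        assert len(xs) == len(set(xs))  # one pixel per column

    def test_bright_band_at_surface_dark_background(self, flat_scene):
        mesh, pose, C = flat_scene
        noise = NoiseSpec(speckle_sigma=0.0, band_intensity=200,
                          background_level=20)
        frame, gt = render_frame(mesh, pose, C, size=(100, 100), noise=noise)
        x, y = gt.pixel_list[len(gt.pixel_list) // 2]
        assert frame.pixels[y, x] >= 200
        assert frame.pixels[5, x] <= 25  # above the surface: background only

    def test_plane_missing_mesh_gives_empty_ground_truth(self, flat_scene):
        mesh, pose, C = flat_scene
        far = Pose(timestamp=0.0, M=pose.M.copy())
        far.M[0, 3] = 500.0
        frame, gt = render_frame(mesh, far, C, size=(50, 50),
                                 noise=NoiseSpec(speckle_sigma=3.0, seed=1))
        assert len(gt.pixel_list) == 0
        assert frame.pixels.shape == (50, 50)

    def test_seeded_render_deterministic(self, flat_scene):
        mesh, pose, C = flat_scene
        n = NoiseSpec(speckle_sigma=5.0, seed=7)
        f1, g1 = render_frame(mesh, pose, C, size=(64, 64), noise=n)
        f2, g2 = render_frame(mesh, pose, C, size=(64, 64), noise=n)
        assert np.array_equal(f1.pixels, f2.pixels)
        assert np.array_equal(g1.pixels, g2.pixels)

    def test_ground_truth_single_run_per_column(self, phantom_mesh):
        C = CalibrationMatrix.from_pixel_spacing(0.1, center_u=80)
        pose = make_sweep_poses(SweepSpec(n_frames=3, jitter_pos_sigma=0,
                                          jitter_rot_sigma=0))[1]
        _, gt = render_frame(phantom_mesh, pose, C, size=(160, 160),
                             noise=NoiseSpec(speckle_sigma=0.0))
        assert len(gt.pixel_list) > 0
        for j in range(gt.pixels.shape[1]):
            nz = np.flatnonzero(gt.pixels[:, j])
            if len(nz):
                assert np.array_equal(nz, np.arange(nz[0], nz[-1] + 1))


class TestSimulateScan:
    def test_dataset_cardinality(self, noiseless_dataset):
        ds = noiseless_dataset
        assert len(list(ds.frames_dir.glob("*.png"))) == ds.n_frames
        assert len(list(ds.masks_dir.glob("*.png"))) == ds.n_frames
        with open(ds.poses_path) as fh:
            assert sum(1 for _ in fh) == ds.n_frames + 1  # header + rows
        assert ds.reference_path.exists() and ds.manifest_path.exists()

    def test_rerun_pose_csv_byte_identical(self, tmp_path, noiseless_dataset):
        from fus3d import simulate_scan
        sweep = SweepSpec(n_frames=5, seed=5)
        noise = NoiseSpec(seed=6)
        a = simulate_scan(sweep=sweep, noise=noise, out_dir=tmp_path / "a",
                          frame_size=(64, 64))
        b = simulate_scan(sweep=sweep, noise=noise, out_dir=tmp_path / "b",
                          frame_size=(64, 64))
        assert a.poses_path.read_bytes() == b.poses_path.read_bytes()
        assert ((a.frames_dir / "frame_0002.png").read_bytes()
                == (b.frames_dir / "frame_0002.png").read_bytes())

    def test_ground_truth_cloud_lies_on_mesh(self, noiseless_dataset):
        """Noiseless, jitter-free reconstruction from ground-truth masks stays
        within one pixel spacing of the mesh (discretization bound)."""
        from fus3d import io as fio
        from fus3d.segmentation import USFrame
        ds = noiseless_dataset
        mesh = fio.read_mesh(ds.reference_path)
        C = fio.load_calibration(ds.calibration_path)
        poses = fio.load_pose_csv(ds.poses_path)
        frames = []
        masks = []
        for k in range(ds.n_frames):
            frames.append(USFrame(fio.read_frame(ds.frames_dir / f"frame_{k:04d}.png"),
                                  timestamp=poses[k].timestamp, frame_index=k))
            masks.append(fio.read_frame(ds.masks_dir / f"mask_{k:04d}.png"))
        pairs = pair_frames_with_poses([f.timestamp for f in frames], poses)
        cloud = reconstruct_cloud(frames, masks, C, pairs)
        assert len(cloud) == sum(int((m != 0).sum()) for m in masks)
        dist = cloud_to_mesh_distances(cloud, mesh, signed=False)
        assert np.abs(dist.d).max() <= C.pixel_spacing + 1e-9
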