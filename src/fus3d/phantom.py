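"""Synthetic phantom, freehand sweep and B-mode frame simulator.

Provides everything the pipeline needs without scanner hardware: a CAD-like
rigid phantom mesh assembled from watertight primitives (boxes, cylinders and
an arch-shaped tube standing in for a dental arch) with a rectangular scaling
landmark of known length (15 mm by default); a freehand sweep of probe poses
at the scanner's 33 frames/s with seeded Gaussian positional/rotational
jitter; and simulated B-mode frames showing what a linear probe sees over a
rigid immersed object — a bright band along the topmost surface, attenuation
(shadowing) below it, and additive speckle-like noise.

Each rendered frame comes with its ground-truth upper envelope (the exact
topmost mesh intersection per image column), so every later stage can be
validated against known geometry.  All randomness is seeded and every run is
reproducible from the manifest.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import trimesh
import yaml
from scipy.spatial.transform import Rotation

from .segmentation import USFrame
from .envelope import EnvelopeMask
from .reconstruction import Pose, CalibrationMatrix

__all__ = [
    "Box",
    "Cylinder",
    "Arch",
    "PhantomSpec",
    "SweepSpec",
    "NoiseSpec",
    "default_phantom_spec",
    "make_phantom_mesh",
    "phantom_components",
    "make_sweep_poses",
    "render_frame",
    "simulate_scan",
    "SimulatedDataset",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

def _translation(offset: Sequence[float]) -> np.ndarray:
    T = np.eye(4)
    T[:3, 3] = offset
    return T


@dataclass
class Box:
    extents: Tuple[float, float, float]
    transform: np.ndarray = field(default_factory=lambda: np.eye(4))

    def build(self) -> trimesh.Trimesh:
        if min(self.extents) <= 0:
            raise ValueError(f"degenerate box extents {self.extents}")
        return trimesh.creation.box(extents=self.extents, transform=self.transform)


@dataclass
class Cylinder:
    radius: float
    height: float
    transform: np.ndarray = field(default_factory=lambda: np.eye(4))

    def build(self) -> trimesh.Trimesh:
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("degenerate cylinder dimensions")
        return trimesh.creation.cylinder(
            radius=self.radius, height=self.height, transform=self.transform,
            sections=64)


@dataclass
class Arch:
    """Annular tube segment (dental-arch stand-in); axis is local z."""

    inner_radius: float
    outer_radius: float
    height: float
    transform: np.ndarray = field(default_factory=lambda: np.eye(4))

    def build(self) -> trimesh.Trimesh:
        if not (0 < self.inner_radius < self.outer_radius) or self.height <= 0:
            raise ValueError("degenerate arch dimensions")
        return trimesh.creation.annulus(
            r_min=self.inner_radius, r_max=self.outer_radius,
            height=self.height, transform=self.transform, sections=64)


@dataclass
class PhantomSpec:
    """Primitive list plus the rectangular scaling landmark.

    The landmark is a bar of ``landmark_length`` × ``landmark_section`` ×
    ``landmark_section`` mm (length along x), the synthetic counterpart of the
    physical 15 mm scaling fixture.
    """

    primitives: List = field(default_factory=list)
    landmark_length: float = 15.0
    landmark_section: float = 3.0
    landmark_offset: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    include_landmark: bool = False

    def landmark_primitive(self) -> Box:
        if self.landmark_length <= 0 or self.landmark_section <= 0:
            raise ValueError("degenerate landmark dimensions")
        return Box(
            extents=(self.landmark_length, self.landmark_section, self.landmark_section),
            transform=_translation(self.landmark_offset),
        )


def default_phantom_spec() -> PhantomSpec:
    """Arch tube + rectangular block + 15 mm landmark bar, laid out along x.

    The sweep direction is +x; top surfaces sit between z ≈ 1.5 and 6 mm so a
    probe travelling above at z ≈ 10 mm sees every component.
    """
    arch = Arch(
        inner_radius=3.5, outer_radius=6.0, height=24.0,
        transform=trimesh.transformations.rotation_matrix(np.pi / 2, [0, 1, 0],
                                                          point=[0, 0, 0])
        @ _translation((0.0, 0.0, 30.0)),  # axis → x, centred at x = 30
    )
    block = Box(extents=(30.0, 10.0, 10.0), transform=_translation((0.0, 0.0, -2.0)))
    return PhantomSpec(
        primitives=[arch, block],
        landmark_length=15.0,
        landmark_section=3.0,
        landmark_offset=(-28.0, 0.0, 0.0),
        include_landmark=True,
    )


def phantom_components(spec: PhantomSpec) -> dict:
    """Build each primitive (and the landmark) as its own watertight mesh."""
    if not spec.primitives and not spec.include_landmark:
        raise ValueError("phantom spec is empty")
    parts = {}
    for k, prim in enumerate(spec.primitives):
        mesh = prim.build()
        if not mesh.is_watertight or mesh.volume <= 0:
            raise ValueError(f"primitive {k} is not a watertight outward-oriented mesh")
        parts[f"{type(prim).__name__.lower()}_{k}"] = mesh
    if spec.include_landmark:
        mesh = spec.landmark_primitive().build()
        if not mesh.is_watertight or mesh.volume <= 0:
            raise ValueError("landmark bar is not watertight")
        parts["landmark"] = mesh
    return parts


def make_phantom_mesh(spec: PhantomSpec) -> trimesh.Trimesh:
    """Triangle mesh of the phantom: concatenation of watertight primitives
    with outward normals, writable as STL."""
    parts = phantom_components(spec)
    return trimesh.util.concatenate(list(parts.values()))


# ---------------------------------------------------------------------------
# sweep poses
# ---------------------------------------------------------------------------

# base probe orientation: image u (columns) → world +y, image v (rows, i.e.
# depth) → world −z, frame normal → world −x; det +1
_BASE_ROTATION = np.array([[0.0, 0.0, -1.0],
                           [1.0, 0.0, 0.0],
                           [0.0, -1.0, 0.0]])


@dataclass
class SweepSpec:
    """A freehand linear sweep above the phantom.

    Defaults mirror a real acquisition: 33 frames/s and ~500 frames per sweep
    (each physical scan produced roughly 450–580 frames).  Jitter sigmas model
    hand wobble that the pose arm records faithfully.
    """

    start: Tuple[float, float, float] = (-40.0, 0.0, 10.0)
    end: Tuple[float, float, float] = (42.0, 0.0, 10.0)
    n_frames: int = 500
    frame_rate: float = 33.0
    jitter_pos_sigma: float = 0.2
    jitter_rot_sigma: float = 0.5
    out_and_back: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.jitter_pos_sigma < 0 or self.jitter_rot_sigma < 0:
            raise ValueError("jitter sigmas must be >= 0")


def make_sweep_poses(spec: SweepSpec) -> List[Pose]:
    """Poses at 1/frame_rate spacing along the (optionally out-and-back)
    linear path, with seeded Gaussian jitter; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    start = np.asarray(spec.start, dtype=float)
    end = np.asarray(spec.end, dtype=float)
    n = spec.n_frames
    poses = []
    for k in range(n):
        frac = 0.0 if n == 1 else k / (n - 1)
        if spec.out_and_back:
            frac = 2 * frac if frac <= 0.5 else 2 * (1 - frac)
        pos = start + frac * (end - start)
        R = _BASE_ROTATION
        if spec.jitter_pos_sigma > 0:
            pos = pos + rng.normal(0.0, spec.jitter_pos_sigma, 3)
        if spec.jitter_rot_sigma > 0:
            wobble = Rotation.from_euler(
                "xyz", rng.normal(0.0, spec.jitter_rot_sigma, 3), degrees=True)
            R = wobble.as_matrix() @ R
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = pos
        poses.append(Pose(timestamp=k / spec.frame_rate, M=M))
    return poses


# ---------------------------------------------------------------------------
# B-mode frame rendering
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """Appearance model of the simulated B-mode frames.

    ``band_intensity`` is the peak brightness added along the surface curve,
    with a Gaussian depth profile of ``band_sigma`` pixels; ``speckle_sigma``
    is the std of the additive noise (the default 5 matches the ~5-intensity
    std of the bright regions that motivates the T ≈ 15 threshold);
    ``shadow_attenuation`` darkens the background exponentially with depth
    below the surface (per mm).
    """

    band_intensity: float = 200.0
    band_sigma: float = 2.0
    speckle_sigma: float = 5.0
    background_level: float = 20.0
    shadow_attenuation: float = 0.1
    seed: int = 0


def _plane_basis(pose: Pose, C: CalibrationMatrix):
    """World origin, in-plane pixel basis vectors and unit normal of a frame."""
    M = pose.M @ C.C
    origin = M[:3, 3]
    eu = M[:3, 0]
    ev = M[:3, 1]
    normal = np.cross(eu, ev)
    normal = normal / np.linalg.norm(normal)
    return origin, eu, ev, normal


def _surface_rows(mesh, pose, C, h, w) -> np.ndarray:
    """Exact sub-pixel row of the topmost mesh intersection per column.

    Returns a float array of length w, NaN where the scan plane misses the
    mesh in that column.  Per column the intersection is interpolated at the
    column's exact u coordinate, so for planar facets the returned point lies
    on the mesh.
    """
    origin, eu, ev, normal = _plane_basis(pose, C)
    v_surf = np.full(w, np.nan)
    try:
        segments = trimesh.intersections.mesh_plane(mesh, normal, origin)
    except Exception:  # no intersection
        return v_surf
    if len(segments) == 0:
        return v_surf
    # world → pixel coordinates within the plane
    G = np.linalg.pinv(np.column_stack([eu, ev]))
    flat = (G @ (segments.reshape(-1, 3) - origin).T).T.reshape(-1, 2, 2)
    for (u1, v1), (u2, v2) in flat:
        if u2 < u1:
            u1, u2, v1, v2 = u2, u1, v2, v1
        if u2 - u1 < 1e-9:  # vertical segment: topmost end in its column
            j = int(round(u1))
            if 0 <= j < w:
                cand = min(v1, v2)
                if np.isnan(v_surf[j]) or cand < v_surf[j]:
                    v_surf[j] = cand
            continue
        j_lo = max(0, int(np.ceil(u1 - 1e-9)))
        j_hi = min(w - 1, int(np.floor(u2 + 1e-9)))
        if j_hi < j_lo:
            continue
        js = np.arange(j_lo, j_hi + 1)
        vs = v1 + (js - u1) * (v2 - v1) / (u2 - u1)
        better = np.isnan(v_surf[js]) | (vs < v_surf[js])
        v_surf[js[better]] = vs[better]
    v_surf[(v_surf < 0) | (v_surf > h - 1)] = np.nan
    return v_surf


def render_frame(
    mesh: trimesh.Trimesh,
    pose: Pose,
    C: CalibrationMatrix,
    size: Tuple[int, int] = (512, 512),
    noise: Optional[NoiseSpec] = None,
    rng: Optional[np.random.Generator] = None,
    timestamp: Optional[float] = None,
    frame_index: int = 0,
) -> Tuple[USFrame, EnvelopeMask]:
    """Render one B-mode frame and its ground-truth upper envelope.

    The frame's image plane is intersected with the mesh; the topmost
    intersection per column defines the ground truth (one envelope pixel per
    column, rounded to the nearest row).  The rendered image is the background
    level, exponentially attenuated below the surface, plus a Gaussian-profile
    bright band centred on the (sub-pixel) surface row, plus seeded additive
    noise; intensities are clipped to [0, 255].  A plane that misses the mesh
    yields a noise-only frame and an empty ground truth.
    """
    noise = noise if noise is not None else NoiseSpec()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    h, w = size
    v_surf = _surface_rows(mesh, pose, C, h, w)

    rows = np.arange(h, dtype=float)[:, None]          # (h,1)
    img = np.full((h, w), float(noise.background_level))
    hit = ~np.isnan(v_surf)
    if hit.any():
        vs = v_surf[hit][None, :]                      # (1,k)
        mm_per_px = float(np.linalg.norm(C.C[:3, 1]))
        depth = np.clip(rows - vs, 0.0, None) * mm_per_px
        atten = np.exp(-noise.shadow_attenuation * depth)
        band = noise.band_intensity * np.exp(-(rows - vs) ** 2
                                             / (2.0 * noise.band_sigma ** 2))
        img[:, hit] = noise.background_level * atten + band
    if noise.speckle_sigma > 0:
        img = img + rng.normal(0.0, noise.speckle_sigma, (h, w))
    frame = USFrame(
        pixels=np.clip(img, 0, 255).astype(np.uint8),
        timestamp=timestamp if timestamp is not None else pose.timestamp,
        frame_index=frame_index,
    )

    gt = np.zeros((h, w), dtype=np.uint8)
    pixel_list = []
    for j in np.nonzero(hit)[0]:
        r = int(round(v_surf[j]))
        if 0 <= r < h:
            gt[r, j] = 255
            pixel_list.append((int(j), r))
    return frame, EnvelopeMask(pixels=gt, pixel_list=pixel_list)


# ---------------------------------------------------------------------------
# full dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Paths of everything :func:`simulate_scan` wrote."""

    root: Path
    frames_dir: Path
    masks_dir: Path
    poses_path: Path
    frame_times_path: Path
    calibration_path: Path
    reference_path: Path
    session_path: Path
    manifest_path: Path
    n_frames: int


def simulate_scan(
    phantom: Optional[PhantomSpec] = None,
    sweep: Optional[SweepSpec] = None,
    noise: Optional[NoiseSpec] = None,
    C: Optional[CalibrationMatrix] = None,
    out_dir: Path = Path("simulated_scan"),
    frame_size: Tuple[int, int] = (512, 512),
) -> SimulatedDataset:
    """Write a complete on-disk dataset consumable by the pipeline CLI.

    Produces frames (PNG), ground-truth envelope masks (PNG), a pose CSV, the
    calibration JSON, the reference STL, a segmentation session file (one seed
    per frame, placed on the ground-truth surface band), and a manifest YAML
    recording every parameter and seed.
    """
    from . import io as fio  # local import to avoid a cycle

    phantom = phantom if phantom is not None else default_phantom_spec()
    sweep = sweep if sweep is not None else SweepSpec()
    noise = noise if noise is not None else NoiseSpec()
    C = (C if C is not None
         else CalibrationMatrix.from_pixel_spacing(0.05, center_u=frame_size[1] / 2))

    out = Path(out_dir)
    frames_dir = out / "frames"
    masks_dir = out / "masks"
    try:
        frames_dir.mkdir(parents=True, exist_ok=True)
        masks_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out}: {exc}") from exc

    mesh = make_phantom_mesh(phantom)
    poses = make_sweep_poses(sweep)
    rng = np.random.default_rng(noise.seed)

    session_frames = {}
    times = []
    for k, pose in enumerate(poses):
        frame, gt = render_frame(mesh, pose, C, size=frame_size, noise=noise,
                                 rng=rng, frame_index=k)
        fio.write_frame(frames_dir / f"frame_{k:04d}.png", frame.pixels)
        fio.write_frame(masks_dir / f"mask_{k:04d}.png", gt.pixels)
        times.append(pose.timestamp)
        if gt.pixel_list:
            x, y = gt.pixel_list[len(gt.pixel_list) // 2]
            session_frames[k] = [{"x": int(x), "y": int(y)}]

    poses_path = out / "poses.csv"
    fio.save_pose_csv(poses, poses_path)
    frame_times_path = out / "frame_times.csv"
    with open(frame_times_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "timestamp", "filename"])
        for k, t in enumerate(times):
            writer.writerow([k, f"{t:.9f}", f"frame_{k:04d}.png"])
    calibration_path = out / "calibration.json"
    fio.save_calibration(C, calibration_path)
    reference_path = out / "reference.stl"
    mesh.export(reference_path)
    session_path = out / "session.yaml"
    with open(session_path, "w") as fh:
        yaml.safe_dump(
            {"defaults": {"T": 15.0, "W": 3, "R": 2, "apply_morph": True},
             "frames": {int(k): v for k, v in session_frames.items()}}, fh)

    manifest = {
        "phantom": {
            "landmark_length": phantom.landmark_length,
            "landmark_section": phantom.landmark_section,
            "landmark_offset": list(phantom.landmark_offset),
            "include_landmark": phantom.include_landmark,
            "n_primitives": len(phantom.primitives),
        },
        "sweep": {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in asdict(sweep).items()},
        "noise": asdict(noise),
        "frame_size": list(frame_size),
        "pixel_spacing_mm": C.pixel_spacing,
        "n_frames": sweep.n_frames,
    }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh)

    logger.info("simulated %d frames into %s", sweep.n_frames, out)
    return SimulatedDataset(
        root=out, frames_dir=frames_dir, masks_dir=masks_dir,
        poses_path=poses_path, frame_times_path=frame_times_path,
        calibration_path=calibration_path, reference_path=reference_path,
        session_path=session_path, manifest_path=manifest_path,
        n_frames=sweep.n_frames,
    )
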