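"""Pose-based 3D reconstruction of a freehand sweep.

Each 2D frame is placed into world space by the chain ``P · C``: the fixed
spatial calibration matrix ``C`` maps pixel coordinates (u, v, 0, 1) — with
the mm/pixel scaling baked in — into the pose sensor's coordinate frame, and
the per-frame pose ``P`` maps the sensor frame into world (mm).  Frames are
paired with the pose reading nearest in time after applying a fixed temporal
latency offset (supplied by the temporal calibration, not estimated here).

The envelope mask of each frame selects which pixels are lifted, producing
the surface point cloud used for accuracy evaluation; an optional voxel
compounding step bins the cloud into an intensity volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .segmentation import USFrame
from .envelope import EnvelopeMask

__all__ = [
    "Pose",
    "CalibrationMatrix",
    "PointCloud3D",
    "VoxelVolume",
    "pair_frames_with_poses",
    "pixel_to_world",
    "reconstruct_cloud",
    "compound_voxels",
]

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-6


def _validate_homogeneous(M: np.ndarray, name: str, check_rotation: bool) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (4, 4):
        raise ValueError(f"{name} must be 4x4, got {M.shape}")
    if not np.allclose(M[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
        raise ValueError(f"{name} last row must be (0, 0, 0, 1)")
    if check_rotation:
        R = M[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError(f"{name} rotation block not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError(f"{name} rotation block must have det +1")
    return M


@dataclass
class Pose:
    """A 6-DOF probe pose: timestamp plus a rigid 4×4 transform (mm)."""

    timestamp: float
    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = _validate_homogeneous(self.M, "pose", check_rotation=True)


@dataclass
class CalibrationMatrix:
    """Spatial calibration: pixel coordinates (u, v, 0, 1) → sensor frame (mm).

    Includes the pixel-spacing scale; must be invertible.  Convenience
    constructor :meth:`from_pixel_spacing` builds the common diagonal-scale
    case.
    """

    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = _validate_homogeneous(self.C, "calibration", check_rotation=False)
        if abs(np.linalg.det(self.C)) < 1e-15:
            raise ValueError("calibration matrix must be invertible")

    @classmethod
    def from_pixel_spacing(
        cls, spacing_mm: float, center_u: float = 0.0
    ) -> "CalibrationMatrix":
        """Isotropic mm/pixel scale; ``center_u`` shifts the lateral origin so
        that column ``center_u`` maps to the sensor axis (u = center_u → 0)."""
        C = np.eye(4)
        C[0, 0] = C[1, 1] = C[2, 2] = spacing_mm
        C[0, 3] = -center_u * spacing_mm
        return cls(C)

    @property
    def pixel_spacing(self) -> float:
        """Mean in-plane scale in mm/pixel (norms of the u and v columns)."""
        return float((np.linalg.norm(self.C[:3, 0]) + np.linalg.norm(self.C[:3, 1])) / 2.0)


@dataclass
class PointCloud3D:
    """Reconstructed surface points (mm) with intensities and provenance.

    ``source`` rows are ``(frame_index, u, v)`` — the pixel each point came
    from; its length always equals the point count.
    """

    points: np.ndarray
    intensities: Optional[np.ndarray] = None
    source: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")
        if self.intensities is not None:
            self.intensities = np.asarray(self.intensities, dtype=float).ravel()
            if len(self.intensities) != len(self.points):
                raise ValueError("intensities length != point count")
        if self.source is not None:
            self.source = np.asarray(self.source, dtype=int).reshape(-1, 3)
            if len(self.source) != len(self.points):
                raise ValueError("provenance length != point count")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class VoxelVolume:
    """Axis-aligned intensity grid compounded from a point cloud."""

    origin: np.ndarray
    voxel_size: float
    grid: np.ndarray

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)


def pair_frames_with_poses(
    frame_timestamps: Sequence[float],
    poses: Sequence[Pose],
    latency: float = 0.0,
    max_gap: float = 1.0 / 33.0,
) -> List[Tuple[int, Pose]]:
    """Match each frame to the pose reading nearest in time.

    The fixed ``latency`` (temporal calibration, seconds) is added to each
    frame timestamp before the nearest-neighbour search.  Pairs whose residual
    gap exceeds ``max_gap`` are dropped with a warning; the default gap is one
    frame period at 33 frames/s.  Pose interpolation is deliberately not
    attempted: readings are paired directly.

    Raises ``ValueError`` if there are no poses, and ``RuntimeError`` if every
    frame is dropped.
    """
    if len(poses) == 0:
        raise ValueError("empty pose list")
    pose_ts = np.array([p.timestamp for p in poses], dtype=float)
    order = np.argsort(pose_ts, kind="stable")
    pose_ts = pose_ts[order]
    sorted_poses = [poses[i] for i in order]

    targets = np.asarray(frame_timestamps, dtype=float) + latency
    idx = np.searchsorted(pose_ts, targets)
    pairs: List[Tuple[int, Pose]] = []
    dropped = 0
    for k, t in enumerate(targets):
        i = idx[k]
        candidates = [c for c in (i - 1, i) if 0 <= c < len(pose_ts)]
        best = min(candidates, key=lambda c: abs(pose_ts[c] - t))
        gap = abs(pose_ts[best] - t)
        if gap > max_gap:
            dropped += 1
            continue
        pairs.append((k, sorted_poses[best]))
    if dropped:
        logger.warning("dropped %d/%d frames with pose gap > %.4f s",
                       dropped, len(targets), max_gap)
    if len(targets) > 0 and not pairs:
        raise RuntimeError("all frames dropped during frame-pose pairing")
    return pairs


def pixel_to_world(
    u: float, v: float, C: CalibrationMatrix, P: Pose
) -> np.ndarray:
    """Map pixel (u = column, v = row) to world mm: first 3 of P·C·(u,v,0,1)ᵀ."""
    p = P.M @ C.C @ np.array([u, v, 0.0, 1.0])
    return p[:3]


def reconstruct_cloud(
    frames: Sequence[USFrame],
    masks: Sequence[Union[EnvelopeMask, np.ndarray]],
    C: CalibrationMatrix,
    paired_poses: Sequence[Tuple[int, Pose]],
) -> PointCloud3D:
    """Lift every nonzero mask pixel of every paired frame into 3D.

    ``masks`` align one-to-one with ``frames`` (EnvelopeMask or bare binary
    arrays).  Point intensities are copied from the frame; points from all
    paired frames are concatenated, with per-point (frame_index, u, v)
    provenance.  No point is invented or lost: the cloud size equals the total
    nonzero mask pixel count over paired frames.
    """
    if len(frames) != len(masks):
        raise ValueError(f"{len(frames)} frames but {len(masks)} masks")
    all_pts, all_int, all_src = [], [], []
    for frame_index, pose in paired_poses:
        frame = frames[frame_index]
        mask = masks[frame_index]
        mask_px = mask.pixels if isinstance(mask, EnvelopeMask) else np.asarray(mask)
        if mask_px.shape != frame.shape:
            raise ValueError(
                f"mask shape {mask_px.shape} != frame shape {frame.shape} "
                f"at index {frame_index}")
        vs, us = np.nonzero(mask_px)
        if len(vs) == 0:
            continue
        homog = np.column_stack([us, vs, np.zeros(len(us)), np.ones(len(us))])
        world = (pose.M @ C.C @ homog.T).T[:, :3]
        all_pts.append(world)
        all_int.append(frame.pixels[vs, us].astype(float))
        all_src.append(np.column_stack([np.full(len(us), frame_index), us, vs]))
    if not all_pts:
        logger.warning("all masks empty: returning empty point cloud")
        return PointCloud3D(points=np.empty((0, 3)),
                            intensities=np.empty(0),
                            source=np.empty((0, 3), dtype=int))
    return PointCloud3D(points=np.vstack(all_pts),
                        intensities=np.concatenate(all_int),
                        source=np.vstack(all_src))


def compound_voxels(
    cloud: PointCloud3D, voxel_size: float, rule: str = "max"
) -> VoxelVolume:
    """Bin the cloud into an intensity voxel grid tight to its bounding box.

    Collisions (several points in one voxel) resolve by maximum intensity
    (``rule="max"``, preserving the bright surface) or by last write
    (``rule="last"``).  Points without intensities count as occupancy 255.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    if len(cloud) == 0:
        raise ValueError("cannot voxelize an empty cloud")
    if rule not in ("max", "last"):
        raise ValueError(f"unknown collision rule {rule!r}")
    origin = cloud.points.min(axis=0)
    ijk = np.floor((cloud.points - origin) / voxel_size).astype(int)
    dims = ijk.max(axis=0) + 1
    grid = np.zeros(dims, dtype=float)
    inten = (cloud.intensities if cloud.intensities is not None
             else np.full(len(cloud), 255.0))
    if rule == "max":
        np.maximum.at(grid, (ijk[:, 0], ijk[:, 1], ijk[:, 2]), inten)
    else:
        grid[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = inten
    return VoxelVolume(origin=origin, voxel_size=voxel_size, grid=grid)
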