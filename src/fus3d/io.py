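"""Readers and writers for the pipeline's on-disk formats.

Frames are 8-bit grayscale PNG/TIFF; label matrices persist as 16-bit PNG;
poses travel as CSV (``timestamp,tx,ty,tz,qx,qy,qz,qw``, quaternion
scalar-last); the spatial calibration is a 4×4 matrix in JSON; meshes are STL
(binary or ASCII on read); clouds are ASCII PLY or XYZ; landmark
correspondences are CSV rows of paired 3D coordinates.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
import trimesh
from PIL import Image
from scipy.spatial.transform import Rotation

from .reconstruction import Pose, CalibrationMatrix, PointCloud3D

__all__ = [
    "read_frame",
    "write_frame",
    "read_label_png",
    "write_label_png",
    "load_pose_csv",
    "save_pose_csv",
    "load_calibration",
    "save_calibration",
    "read_mesh",
    "write_mesh",
    "write_ply",
    "read_ply",
    "write_xyz",
    "read_xyz",
    "load_landmark_pairs",
    "save_landmark_pairs",
]

_QUAT_TOL = 1e-6
POSE_HEADER = ["timestamp", "tx", "ty", "tz", "qx", "qy", "qz", "qw"]


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_frame(path: Union[str, Path]) -> np.ndarray:
    """Read an 8-bit grayscale frame (PNG/TIFF) as a (h, w) uint8 array."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L") if im.mode not in ("L", "I;16") else im)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_frame(path: Union[str, Path], pixels: np.ndarray) -> None:
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError("frame must be 2D")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def read_label_png(path: Union[str, Path]) -> np.ndarray:
    """Read a 16-bit label PNG as an int32 label matrix."""
    with Image.open(path) as im:
        return np.asarray(im, dtype=np.int32)


def write_label_png(path: Union[str, Path], labels: np.ndarray) -> None:
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() > 65535:
        raise ValueError("labels out of 16-bit range")
    Image.fromarray(arr.astype(np.uint16)).save(path)


# ---------------------------------------------------------------------------
# poses and calibration
# ---------------------------------------------------------------------------

def load_pose_csv(path: Union[str, Path]) -> List[Pose]:
    """Parse the pose CSV dialect; quaternions are scalar-last (x, y, z, w).

    Quaternion norms must be within 1e-6 of 1 (they are re-normalized before
    use); rows come back sorted by timestamp.  Malformed rows raise a parse
    error naming the line.
    """
    poses = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip() for c in header] != POSE_HEADER:
            raise ValueError(
                f"{path}: expected header {','.join(POSE_HEADER)}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                vals = [float(x) for x in row]
                if len(vals) != 8:
                    raise ValueError(f"{len(vals)} fields")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed pose row ({exc})") from exc
            t, tx, ty, tz, qx, qy, qz, qw = vals
            q = np.array([qx, qy, qz, qw])
            norm = np.linalg.norm(q)
            if abs(norm - 1.0) > _QUAT_TOL:
                raise ValueError(
                    f"{path}:{lineno}: quaternion norm {norm:.6g} not unit "
                    f"(tolerance {_QUAT_TOL})")
            M = np.eye(4)
            M[:3, :3] = Rotation.from_quat(q / norm).as_matrix()
            M[:3, 3] = (tx, ty, tz)
            poses.append(Pose(timestamp=t, M=M))
    poses.sort(key=lambda p: p.timestamp)
    return poses


def save_pose_csv(poses: Sequence[Pose], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(POSE_HEADER)
        for p in poses:
            q = Rotation.from_matrix(p.M[:3, :3]).as_quat()  # scalar-last
            t = p.M[:3, 3]
            writer.writerow([f"{p.timestamp:.9f}"]
                            + [f"{x:.9f}" for x in t]
                            + [f"{x:.12f}" for x in q])


def load_calibration(path: Union[str, Path]) -> CalibrationMatrix:
    """Load a 4×4 calibration matrix from JSON ({"matrix": [[...]x4]})."""
    with open(path) as fh:
        data = json.load(fh)
    matrix = data["matrix"] if isinstance(data, dict) else data
    return CalibrationMatrix(np.asarray(matrix, dtype=float))


def save_calibration(C: CalibrationMatrix, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump({"matrix": C.C.tolist()}, fh, indent=2)


# ---------------------------------------------------------------------------
# meshes and point clouds
# ---------------------------------------------------------------------------

def read_mesh(path: Union[str, Path]) -> trimesh.Trimesh:
    """Read a triangle mesh (STL binary/ASCII, or anything trimesh handles)."""
    mesh = trimesh.load(path, force="mesh")
    if mesh.is_empty or len(mesh.faces) == 0:
        raise ValueError(f"{path}: no triangles parsed")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: Union[str, Path]) -> None:
    mesh.export(path)


def write_ply(cloud: PointCloud3D, path: Union[str, Path]) -> None:
    """Write the cloud as ASCII PLY with per-vertex intensity."""
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty cloud")
    inten = (cloud.intensities if cloud.intensities is not None
             else np.zeros(len(cloud)))
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("property double intensity\nend_header\n")
        for (x, y, z), c in zip(cloud.points, inten):
            fh.write(f"{x:.9f} {y:.9f} {z:.9f} {c:.3f}\n")


def read_ply(path: Union[str, Path]) -> PointCloud3D:
    """Read an ASCII PLY written by :func:`write_ply` (x, y, z[, intensity])."""
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n_vertex = None
        props = []
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated header")
            line = line.strip()
            if line.startswith("element vertex"):
                n_vertex = int(line.split()[-1])
            elif line.startswith("property"):
                props.append(line.split()[-1])
            elif line == "end_header":
                break
        if n_vertex is None:
            raise ValueError(f"{path}: missing vertex element")
        data = np.loadtxt(fh, max_rows=n_vertex, ndmin=2)
    if data.shape[0] != n_vertex:
        raise ValueError(f"{path}: expected {n_vertex} vertices, got {data.shape[0]}")
    pts = data[:, :3]
    inten = data[:, 3] if data.shape[1] > 3 and "intensity" in props else None
    return PointCloud3D(points=pts, intensities=inten)


def write_xyz(cloud: PointCloud3D, path: Union[str, Path]) -> None:
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty cloud")
    np.savetxt(path, cloud.points, fmt="%.9f")


def read_xyz(path: Union[str, Path]) -> PointCloud3D:
    pts = np.loadtxt(path, ndmin=2)
    return PointCloud3D(points=pts[:, :3])


# ---------------------------------------------------------------------------
# landmark correspondences
# ---------------------------------------------------------------------------

def load_landmark_pairs(path: Union[str, Path]) -> Tuple[np.ndarray, np.ndarray]:
    """CSV rows ``sx,sy,sz,tx,ty,tz`` → (source (n,3), target (n,3))."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {data.shape[1]}")
    return data[:, :3], data[:, 3:]


def save_landmark_pairs(source: np.ndarray, target: np.ndarray,
                        path: Union[str, Path]) -> None:
    source = np.asarray(source).reshape(-1, 3)
    target = np.asarray(target).reshape(-1, 3)
    if len(source) != len(target):
        raise ValueError("source/target landmark counts differ")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sx", "sy", "sz", "tx", "ty", "tz"])
        for s, t in zip(source, target):
            writer.writerow([f"{v:.9f}" for v in (*s, *t)])
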