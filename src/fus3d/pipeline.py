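"""End-to-end pipeline: segment → envelope → reconstruct → align.

One :class:`PipelineConfig` (loadable from YAML) drives the full run;
intermediate artifacts (segmentation masks, envelope masks and pixel lists,
the point cloud) are persisted so any stage can be inspected or re-entered,
and a JSON report with the alignment statistics is written at the end.  Every
stage appends a record (parameters, counts, warnings) to the run log, and
stage failures abort with an error naming the stage while keeping partial
outputs on disk for debugging.

Counts obey conservation: envelope mask pixels = cloud points = distance
count (when no cutoff is applied).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import io as fio
from .segmentation import USFrame, SegParams, grow_region
from .envelope import find_upper_envelope, EnvelopeMask
from .reconstruction import (CalibrationMatrix, pair_frames_with_poses,
                             reconstruct_cloud, PointCloud3D)
from .alignment import (SimilarityTransform, estimate_similarity_from_pairs,
                        icp_refine, cloud_to_mesh_distances, summarize_alignment)

__all__ = ["PipelineConfig", "PipelineError", "RunLog", "run_pipeline",
           "segment_frames", "load_session"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failure; ``stage`` names where it happened."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and stage parameters of one reproducible pipeline run."""

    frames_dir: Path
    poses_path: Path
    calibration_path: Path
    reference_path: Path
    output_dir: Path
    frame_times_path: Optional[Path] = None
    session_path: Optional[Path] = None       # segmentation seeds
    masks_dir: Optional[Path] = None          # pre-made envelope masks
    landmarks_path: Optional[Path] = None     # rough-alignment pairs
    skip_segmentation: bool = False           # use masks_dir directly
    latency: float = 0.0
    max_gap: float = 1.0 / 33.0
    seg: SegParams = field(default_factory=SegParams)
    voxel_size: float = 0.1
    icp_tol: float = 1e-6
    icp_max_iter: int = 100
    with_scale: bool = True
    signed: bool = True
    max_distance: Optional[float] = None      # optional outlier cutoff, mm
    write_distances: bool = False

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        seg = SegParams(**raw.pop("seg", {}))
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {k: (Path(v) if k.endswith(("_dir", "_path")) and v is not None else v)
                  for k, v in raw.items()}
        return cls(seg=seg, **kwargs)


@dataclass
class RunLog:
    """Append-only, timestamped per-stage records."""

    records: List[dict] = field(default_factory=list)

    def add(self, stage: str, **info) -> None:
        self.records.append({"stage": stage, "time": time.time(), **info})

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.records, fh, indent=2, default=str)


def load_session(path: Path) -> Tuple[dict, Dict[int, List[dict]]]:
    """Load a segmentation session: global defaults plus per-frame seed lists.

    Each seed is ``{"x": int, "y": int}`` with optional per-seed overrides of
    ``T``, ``R`` and ``apply_morph``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    defaults = raw.get("defaults", {})
    frames = {int(k): v for k, v in raw.get("frames", {}).items()}
    return defaults, frames


def _frame_files(frames_dir: Path) -> List[Path]:
    files = sorted(p for p in Path(frames_dir).iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not files:
        raise FileNotFoundError(f"no frames in {frames_dir}")
    return files


def _load_frames(cfg: PipelineConfig) -> List[USFrame]:
    files = _frame_files(cfg.frames_dir)
    times = {}
    if cfg.frame_times_path is not None:
        with open(cfg.frame_times_path, newline="") as fh:
            for row in csv.DictReader(fh):
                times[int(row["frame_index"])] = float(row["timestamp"])
    frames = []
    for k, path in enumerate(files):
        frames.append(USFrame(pixels=fio.read_frame(path),
                              timestamp=times.get(k, float(k)),
                              frame_index=k))
    return frames


def segment_frames(
    frames: List[USFrame],
    defaults: dict,
    seeds_by_frame: Dict[int, List[dict]],
) -> List[np.ndarray]:
    """Run seeded region growing on every frame with seeds.

    Per frame, each seed grows into a fresh local matrix constrained by the
    frame's accumulating global matrix, then merges into it; frames without
    seeds yield empty masks.  Returns one binary (0/255) mask per frame.
    """
    masks = []
    base = {k: defaults[k] for k in ("T", "W", "R", "label", "apply_morph")
            if k in defaults}
    for frame in frames:
        glob = np.zeros(frame.shape, dtype=np.int32)
        for seed in seeds_by_frame.get(frame.frame_index, []):
            params = SegParams(**{**base,
                                  **{k: seed[k] for k in ("T", "R", "apply_morph")
                                     if k in seed}})
            local = np.zeros_like(glob)
            local = grow_region(frame, local, glob, (seed["x"], seed["y"]), params)
            glob[(glob == 0) & (local != 0)] = local[(glob == 0) & (local != 0)]
        masks.append(((glob != 0) * 255).astype(np.uint8))
    return masks


def run_pipeline(config: PipelineConfig) -> "AlignmentReport":
    """Execute the full pipeline and return the final alignment report."""
    from .alignment import AlignmentReport  # noqa: F401 (return type)

    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()

    # ---- inputs ----------------------------------------------------------
    stage = "load"
    try:
        for name, p in (("frames_dir", cfg.frames_dir),
                        ("poses", cfg.poses_path),
                        ("calibration", cfg.calibration_path),
                        ("reference", cfg.reference_path)):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"missing {name}: {p}")
        frames = _load_frames(cfg)
        poses = fio.load_pose_csv(cfg.poses_path)
        C = fio.load_calibration(cfg.calibration_path)
        mesh = fio.read_mesh(cfg.reference_path)
        log.add(stage, frames_read=len(frames), poses_read=len(poses),
                reference_triangles=len(mesh.faces))
    except Exception as exc:
        log.save(out / "run_log.json")
        raise PipelineError(stage, str(exc)) from exc

    # ---- segmentation ----------------------------------------------------
    stage = "segment"
    try:
        if cfg.skip_segmentation:
            if cfg.masks_dir is None:
                raise ValueError("skip_segmentation requires masks_dir")
            mask_files = _frame_files(cfg.masks_dir)
            if len(mask_files) != len(frames):
                raise ValueError(f"{len(mask_files)} masks for {len(frames)} frames")
            seg_masks = [fio.read_frame(p) for p in mask_files]
            log.add(stage, skipped=True, masks_loaded=len(seg_masks))
        else:
            if cfg.session_path is None:
                raise ValueError("segmentation requires a session file with seeds")
            defaults, seeds = load_session(cfg.session_path)
            seg_masks = segment_frames(frames, defaults, seeds)
            seg_dir = out / "segmentation"
            seg_dir.mkdir(exist_ok=True)
            for k, m in enumerate(seg_masks):
                fio.write_label_png(seg_dir / f"seg_{k:04d}.png", (m != 0).astype(int))
            log.add(stage, frames_segmented=len(seg_masks),
                    labeled_pixels=int(sum((m != 0).sum() for m in seg_masks)))
    except Exception as exc:
        log.save(out / "run_log.json")
        raise PipelineError(stage, str(exc)) from exc

    # ---- envelope --------------------------------------------------------
    stage = "envelope"
    try:
        if cfg.skip_segmentation:
            # pre-made masks are taken as envelopes already
            envelopes = [EnvelopeMask(
                pixels=(np.asarray(m) != 0).astype(np.uint8) * 255,
                pixel_list=[(int(x), int(y)) for y, x in
                            zip(*np.nonzero(np.asarray(m)))])
                for m in seg_masks]
        else:
            envelopes = [find_upper_envelope(m) for m in seg_masks]
            env_dir = out / "envelopes"
            env_dir.mkdir(exist_ok=True)
            with open(out / "envelope_pixels.csv", "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["frame_index", "x", "y"])
                for k, env in enumerate(envelopes):
                    fio.write_frame(env_dir / f"env_{k:04d}.png", env.pixels)
                    for x, y in env.pixel_list:
                        writer.writerow([k, x, y])
        env_pixels = int(sum((e.pixels != 0).sum() for e in envelopes))
        log.add(stage, envelope_pixels=env_pixels)
    except Exception as exc:
        log.save(out / "run_log.json")
        raise PipelineError(stage, str(exc)) from exc

    # ---- reconstruction --------------------------------------------------
    stage = "reconstruct"
    try:
        pairs = pair_frames_with_poses([f.timestamp for f in frames], poses,
                                       latency=cfg.latency, max_gap=cfg.max_gap)
        cloud = reconstruct_cloud(frames, envelopes, C, pairs)
        if len(cloud) == 0:
            raise ValueError("reconstruction produced an empty cloud")
        fio.write_ply(cloud, out / "cloud.ply")
        log.add(stage, frames_paired=len(pairs),
                frames_dropped=len(frames) - len(pairs), points=len(cloud))
        if len(cloud) != env_pixels:
            logger.warning("conservation: %d cloud points vs %d envelope pixels "
                           "(frames dropped during pairing)", len(cloud), env_pixels)
    except Exception as exc:
        log.save(out / "run_log.json")
        raise PipelineError(stage, str(exc)) from exc

    # ---- alignment -------------------------------------------------------
    stage = "align"
    try:
        if cfg.landmarks_path is not None:
            src, dst = fio.load_landmark_pairs(cfg.landmarks_path)
            init = estimate_similarity_from_pairs(src, dst)
        else:
            init = SimilarityTransform.identity()
        transform, report = icp_refine(
            cloud, mesh, init=init, with_scale=cfg.with_scale,
            tol=cfg.icp_tol, max_iter=cfg.icp_max_iter, signed=cfg.signed)
        if cfg.max_distance is not None:
            ds = cloud_to_mesh_distances(transform.apply(cloud.points), mesh,
                                         signed=cfg.signed)
            keep = np.abs(ds.d) <= cfg.max_distance
            ds.d = ds.d[keep]
            report = summarize_alignment(ds, transform=transform,
                                         iterations=report.iterations,
                                         converged=report.converged)
        payload = {"schema_version": REPORT_SCHEMA_VERSION, **report.to_dict()}
        with open(out / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        if cfg.write_distances:
            ds = cloud_to_mesh_distances(transform.apply(cloud.points), mesh,
                                         signed=cfg.signed)
            np.savetxt(out / "distances.csv", ds.d, fmt="%.9f",
                       header="distance_mm", comments="")
        log.add(stage, n_distances=report.n, rms_mm=report.rms,
                mean_mm=report.mean_distance, std_mm=report.std_deviation,
                iterations=report.iterations, converged=report.converged)
    except Exception as exc:
        log.save(out / "run_log.json")
        raise PipelineError(stage, str(exc)) from exc

    log.save(out / "run_log.json")
    logger.info("pipeline done: n=%d, mean=%.4f mm, std=%.4f mm, rms=%.4f mm",
                report.n, report.mean_distance, report.std_deviation, report.rms)
    return report
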