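"""Label-constrained semi-automatic segmentation of 2D B-mode frames.

The bright surface band of the scanned phantom is segmented by seeded region
growing: starting from an operator-supplied seed pixel, neighbouring pixels are
absorbed while their intensity stays within a threshold ``T`` of the running
mean intensity of the grown region.  Growth is *label constrained*: a pixel
already labelled in either the local (current session) or global (accumulated)
label matrix is never absorbed, so repeated seeding cannot overwrite earlier
work and the same machinery supports multi-label annotation.

An optional morphological closing (dilation followed by erosion with the same
structuring element) fills small holes left by speckle.  The morphology is
also label constrained and deliberately literal: pixels within ``R`` of the
image border are never modified (a safety border, rather than the more common
pad-and-process convention), and for radii above 2 the structuring element is
the open Euclidean disc {(m, n) : sqrt(m² + n²) < R}; for R ≤ 2 it is the full
(2R+1)² square.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "USFrame",
    "SegParams",
    "recommend_threshold",
    "grow_region",
    "dilate_label",
    "erode_label",
    "close_label",
    "structuring_offsets",
]


@dataclass
class USFrame:
    """One 2D grayscale ultrasound frame.

    Attributes
    ----------
    pixels
        ``(h, w)`` array of intensities in [0, 255], origin top-left.
    timestamp
        Acquisition time in seconds (used for frame–pose pairing).
    frame_index
        Position of the frame within its sweep.
    """

    pixels: np.ndarray
    timestamp: float = 0.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("frame must be a non-empty 2D array")
        lo, hi = self.pixels.min(), self.pixels.max()
        if lo < 0 or hi > 255:
            raise ValueError(f"intensities must lie in [0, 255], got [{lo}, {hi}]")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass
class SegParams:
    """Parameters of the region-growing segmentation.

    ``T`` is the intensity-difference threshold of the similarity predicate
    |color − avg| < T.  A good starting point is 2σ–3σ where σ is the
    intensity standard deviation of the target region (see
    :func:`recommend_threshold`); the default 15 corresponds to σ ≈ 5 for the
    whitish surface band of the phantom.  ``W`` is the (odd) side of the
    window averaged around the seed to initialise the region mean.  ``R`` is
    the structuring-element radius of the optional closing.
    """

    T: float = 15.0
    W: int = 3
    R: int = 2
    label: int = 1
    apply_morph: bool = False
    sigma_roi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.W < 1 or self.W % 2 == 0:
            raise ValueError("W must be odd and >= 1")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.label < 1:
            raise ValueError("label must be >= 1")


def recommend_threshold(sigma_roi: float) -> Tuple[float, float]:
    """Return the recommended ``T`` interval ``[2σ, 3σ]`` for a region whose
    intensity standard deviation is ``sigma_roi``."""
    if sigma_roi <= 0:
        raise ValueError("sigma_roi must be > 0")
    return 2.0 * sigma_roi, 3.0 * sigma_roi


def _as_pixels(frame) -> np.ndarray:
    return frame.pixels if isinstance(frame, USFrame) else np.asarray(frame)


def grow_region(
    frame,
    local: np.ndarray,
    global_: Optional[np.ndarray],
    seed: Tuple[int, int],
    params: SegParams,
) -> np.ndarray:
    """Grow a labelled region from ``seed`` and return the updated local matrix.

    Breadth-first search with a FIFO queue.  The region mean is initialised as
    the average of the ``W``×``W`` window centred on the seed (clipped at the
    image border) and updated incrementally as pixels are absorbed (on
    enqueue).  A pixel is absorbed iff it is 8-connected to an absorbed pixel,
    |color − avg| < T (strict), and it is unlabelled (0) in *both* the local
    and global matrices.  The seed pixel itself is labelled only if currently
    unlabelled, but growth proceeds from it regardless.

    Parameters
    ----------
    frame
        :class:`USFrame` or bare 2D array.
    local, global_
        Integer label matrices of the frame's shape; ``global_`` may be None
        (treated as all-unlabelled).  Inputs are not modified.
    seed
        ``(x, y)`` pixel coordinate, x = column, y = row.
    params
        :class:`SegParams`; ``params.apply_morph`` triggers a closing with
        radius ``params.R`` on the grown label.
    """
    src = _as_pixels(frame)
    h, w = src.shape
    x, y = int(seed[0]), int(seed[1])
    if not (0 <= x < w and 0 <= y < h):
        raise IndexError(f"seed ({x}, {y}) outside {h}x{w} image")
    labels = np.array(local, dtype=np.int32, copy=True)
    if labels.shape != src.shape:
        raise ValueError(f"local labels shape {labels.shape} != frame {src.shape}")
    if global_ is None:
        glabels = np.zeros_like(labels)
    else:
        glabels = np.asarray(global_)
        if glabels.shape != src.shape:
            raise ValueError(f"global labels shape {glabels.shape} != frame {src.shape}")

    half = params.W // 2
    win = src[max(0, y - half): y + half + 1, max(0, x - half): x + half + 1]
    avg_color = float(win.mean())
    n = 1
    q: deque = deque()
    q.append((y, x))
    if labels[y, x] == 0:
        labels[y, x] = params.label

    pix = src  # local alias; ints compare exactly
    t = params.T
    lab = params.label
    while q:
        oy, ox = q.popleft()
        for m in (-1, 0, 1):
            i = oy + m
            if i < 0 or i >= h:
                continue
            for nn in (-1, 0, 1):
                j = ox + nn
                if j < 0 or j >= w:
                    continue
                if labels[i, j] != 0 or glabels[i, j] != 0:
                    continue
                color = float(pix[i, j])
                if abs(color - avg_color) < t:
                    labels[i, j] = lab
                    q.append((i, j))
                    avg_color = (avg_color * n + color) / (n + 1)
                    n += 1

    if params.apply_morph:
        labels = dilate_label(labels, params.R, lab)
        labels = erode_label(labels, params.R, lab)
    return labels


def structuring_offsets(R: int) -> np.ndarray:
    """Offsets ``(m, n)`` of the structuring element of radius ``R``.

    R ≤ 2 → the full (2R+1)² square; R > 2 → the open Euclidean disc
    sqrt(m² + n²) < R.  For R = 4 the disc has 45 pixels (the 7×7 square minus
    its four corners).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    mm, nn = np.mgrid[-R: R + 1, -R: R + 1]
    if R > 2:
        keep = np.hypot(mm, nn) < R
    else:
        keep = np.ones_like(mm, dtype=bool)
    return np.stack([mm[keep], nn[keep]], axis=1)


def _check_morph_input(labels: np.ndarray, R: int) -> np.ndarray:
    if R < 1:
        raise ValueError("R must be >= 1")
    arr = np.asarray(labels)
    if arr.ndim != 2:
        raise ValueError("label matrix must be 2D")
    return arr


def dilate_label(labels: np.ndarray, R: int, label: int = 1) -> np.ndarray:
    """Label-constrained dilation.

    Every background (0) pixel inside the structuring element of a pixel
    carrying ``label`` is set to ``label``.  Only source pixels in the safety
    border ``[R, h−R−1] × [R, w−R−1]`` act, so nothing nearer than ``R`` to the
    edge is ever modified; pixels carrying other labels are never overwritten.
    """
    src = _check_morph_input(labels, R)
    dst = src.copy()
    h, w = src.shape
    if h < 2 * R + 1 or w < 2 * R + 1:
        return dst  # scan range empty
    core = src[R: h - R, R: w - R] == label
    if not core.any():
        return dst
    for m, n in structuring_offsets(R):
        shifted_src = src[R + m: h - R + m, R + n: w - R + n]
        target = dst[R + m: h - R + m, R + n: w - R + n]
        target[core & (shifted_src == 0)] = label
    return dst


def erode_label(labels: np.ndarray, R: int, label: int = 1) -> np.ndarray:
    """Label-constrained erosion.

    A pixel carrying ``label`` is cleared to 0 iff any background (0) pixel
    lies inside its structuring element.  Same element and safety border as
    :func:`dilate_label`; the output label set is a subset of the input's.
    """
    src = _check_morph_input(labels, R)
    dst = src.copy()
    h, w = src.shape
    if h < 2 * R + 1 or w < 2 * R + 1:
        return dst
    core = src[R: h - R, R: w - R] == label
    if not core.any():
        return dst
    frontier = np.zeros_like(core)
    for m, n in structuring_offsets(R):
        shifted_src = src[R + m: h - R + m, R + n: w - R + n]
        frontier |= core & (shifted_src == 0)
    view = dst[R: h - R, R: w - R]
    view[frontier] = 0
    return dst


def close_label(labels: np.ndarray, R: int, label: int = 1) -> np.ndarray:
    """Morphological closing: dilation then erosion with the same element.

    Fills holes smaller than the structuring element; extensive (output ⊇
    input) and idempotent.
    """
    return erode_label(dilate_label(labels, R, label), R, label)
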