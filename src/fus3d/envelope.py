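"""External contours and the upper envelope of segmented binary frames.

In a B-mode section of a rigid object only the outer (upper) surface reflects
strongly, so the quantity of interest in each segmented frame is the *upper
envelope*: per image column, the first (topmost) vertical run of contour
pixels.  The envelope is what gets lifted into 3D by the reconstruction stage.

Contour extraction is external-only: the outline of each 8-connected
foreground component is marked, while boundaries of interior holes are not.
It is computed here from first principles (a foreground pixel is an external
contour pixel iff it is 8-adjacent to the background region connected to the
image border), which is equivalent to external border following.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage

__all__ = ["EnvelopeMask", "find_external_contours", "find_upper_envelope"]

_FG = 255


@dataclass
class EnvelopeMask:
    """Binary upper-envelope image plus the ordered list of its pixels.

    ``pixels`` is 0/255; ``pixel_list`` holds ``(x, y)`` coordinates in
    column-major scan order (the order Algorithmic scanning visits them).
    Per column the nonzero pixels form at most one contiguous vertical run.
    """

    pixels: np.ndarray
    pixel_list: List[Tuple[int, int]]

    def __len__(self) -> int:
        return len(self.pixel_list)


def find_external_contours(binary: np.ndarray) -> np.ndarray:
    """Mark the external boundary pixels of every foreground component.

    Foreground is any nonzero pixel.  A pixel belongs to the external contour
    iff it is foreground and 8-adjacent to "outside" background — the
    background region 4-connected to the image border (the image is padded by
    one background ring so components touching the border still get their
    outline).  Interior holes are thereby excluded: their surrounding
    background cannot reach the border.

    Returns a uint8 image, contour pixels 255.
    """
    arr = np.asarray(binary)
    if arr.ndim != 2:
        raise ValueError("input must be 2D")
    fg = arr != 0
    out = np.zeros(arr.shape, dtype=np.uint8)
    if not fg.any():
        return out
    padded_bg = np.pad(~fg, 1, constant_values=True)
    # 4-connected background labelling: complement duality of 8-connected fg
    bg_labels, _ = ndimage.label(padded_bg, structure=np.array([[0, 1, 0],
                                                                [1, 1, 1],
                                                                [0, 1, 0]]))
    outside = bg_labels == bg_labels[0, 0]
    near_outside = ndimage.binary_dilation(outside, structure=np.ones((3, 3)))
    contour = fg & near_outside[1:-1, 1:-1]
    out[contour] = _FG
    return out


def find_upper_envelope(binary: np.ndarray) -> EnvelopeMask:
    """Extract the upper envelope of a segmented binary image.

    External contours are extracted first; the contour image is then scanned
    column by column, top to bottom (the row index restarts at 0 for every
    column): leading background is skipped, the first contiguous vertical run
    of contour pixels is copied to the output, and the rest of the column is
    ignored.  Keeping the whole run (not just its first pixel) preserves
    vertical contour segments that belong to the envelope.

    The scan guards mirror the pseudocode bound ``i < h − 1`` exactly, so a
    run confined to the very last image row is not recorded.

    Columns without foreground contribute nothing.
    """
    contours = find_external_contours(binary)
    h, w = contours.shape
    dst = np.zeros((h, w), dtype=np.uint8)
    pixel_list: List[Tuple[int, int]] = []
    for j in range(w):
        i = 0
        while contours[i, j] == 0 and i < h - 1:
            i += 1
        while contours[i, j] == _FG and i < h - 1:
            dst[i, j] = _FG
            pixel_list.append((j, i))
            i += 1
    return EnvelopeMask(pixels=dst, pixel_list=pixel_list)
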