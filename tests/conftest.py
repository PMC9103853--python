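import numpy as np
import pytest
from scipy import ndimage

from fus3d import (CalibrationMatrix, NoiseSpec, SweepSpec,
                   default_phantom_spec, make_phantom_mesh, simulate_scan)

EIGHT = np.ones((3, 3), dtype=int)


@pytest.fixture(scope="session")
def phantom_mesh():
    return make_phantom_mesh(default_phantom_spec())


@pytest.fixture(scope="session")
def noiseless_dataset(tmp_path_factory):
    """Small noiseless, jitter-free simulated sweep reused across tests."""
    out = tmp_path_factory.mktemp("sim_noiseless")
    sweep = SweepSpec(n_frames=40, jitter_pos_sigma=0.0, jitter_rot_sigma=0.0,
                      seed=5)
    noise = NoiseSpec(speckle_sigma=0.0, seed=6)
    C = CalibrationMatrix.from_pixel_spacing(0.1, center_u=80)
    return simulate_scan(default_phantom_spec(), sweep, noise, C,
                         out_dir=out, frame_size=(160, 160))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def flood_fill_same_value(image: np.ndarray, seed_xy) -> np.ndarray:
    """8-connected component of pixels sharing the seed's exact value."""
    x, y = seed_xy
    same = image == image[y, x]
    comp, _ = ndimage.label(same, structure=EIGHT)
    return comp == comp[y, x]


def boundary_of_holefree(fg: np.ndarray) -> np.ndarray:
    """External boundary of a hole-free foreground: fg minus its 3×3 erosion
    (outside the image counts as background)."""
    eroded = ndimage.binary_erosion(fg, structure=EIGHT, border_value=0)
    return fg & ~eroded


def first_run_per_column(contour: np.ndarray) -> np.ndarray:
    """Per column: the first contiguous vertical run of nonzero pixels,
    scanning rows [0, h−2] (the last row is outside the scan bound)."""
    h, w = contour.shape
    out = np.zeros_like(contour, dtype=bool)
    for j in range(w):
        col = contour[: h - 1, j] != 0
        nz = np.flatnonzero(col)
        if len(nz) == 0:
            continue
        i = nz[0]
        while i < h - 1 and contour[i, j] != 0:
            out[i, j] = True
            i += 1
    return out


def random_blobs(rng, shape=(48, 48), n_blobs=3) -> np.ndarray:
    """Random hole-free binary image: union of filled discs."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    fg = np.zeros(shape, dtype=bool)
    for _ in range(n_blobs):
        cy, cx = rng.integers(8, h - 8), rng.integers(8, w - 8)
        r = rng.integers(3, 9)
        fg |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    return ndimage.binary_fill_holes(fg)


def random_piecewise_constant(rng, shape=(40, 40), n_rects=4, spacing=50):
    """Image of overlapping constant rectangles with pairwise contrast >=
    ``spacing``, plus a seed whose 3×3 window is single-valued."""
    img = np.zeros(shape, dtype=np.uint8)
    values = rng.permutation(np.arange(1, 5)) * spacing
    for v in values[:n_rects]:
        y0 = rng.integers(0, shape[0] - 8)
        x0 = rng.integers(0, shape[1] - 8)
        img[y0: y0 + rng.integers(5, 20), x0: x0 + rng.integers(5, 20)] = v
    # seed with a constant 3x3 neighbourhood (interior of some region)
    for _ in range(1000):
        y = rng.integers(1, shape[0] - 1)
        x = rng.integers(1, shape[1] - 1)
        win = img[y - 1: y + 2, x - 1: x + 2]
        if (win == img[y, x]).all():
            return img, (x, y)
    pytest.skip("could not place a seed with a constant window")
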