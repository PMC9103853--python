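# Methods

This note records the models, conventions and numerical choices behind
`fus3d`, and what the synthetic validation does and does not demonstrate.

## Segmentation

Region growing is a breadth-first traversal with a FIFO queue.  The running
mean μ is seeded with the average of the W×W window centred on the seed
(W = 3 by default; the window is clipped at image borders and averaged over
the valid pixels) and updated incrementally *when a pixel is enqueued*, not
dequeued.  The similarity predicate is strict, |I − μ| < T, so T = 0 grows
nothing beyond the seed.  The 3×3 neighbourhood scan includes the centre
cell, a harmless no-op.  The seed itself is labelled only if currently
unlabelled, but growth proceeds from it regardless — repeated seeding of an
already-labelled point re-examines its neighbourhood without duplicating
labels.

T defaults to 15: a sensible threshold is 2σ–3σ of the target region's
intensity noise, and the bright surface band in our frames has σ ≈ 5
(matched by the simulator's speckle default).  `recommend_threshold(sigma)`
returns this band.  The interactive threshold slider of an operator-driven
tool is replaced by per-seed `T` overrides in a session file, which makes
batch runs reproducible.

Label constraint: a pixel nonzero in either the local (current seed) or
global (accumulated) matrix is never absorbed, so multi-seed sessions are
order-independent in coverage and the machinery extends to multi-label
annotation unchanged.

### Morphology

Dilation and erosion are label-constrained and deliberately literal:

- structuring element: for R ≤ 2 the full (2R+1)² square, for R > 2 the open
  Euclidean disc {(m, n) : √(m²+n²) < R} (45 offsets at R = 4);
- *safety border*: only source pixels with indices in [R, h−R−1] × [R, w−R−1]
  act, and consequently nothing within R of the image edge is ever modified.
  This differs from the common pad-and-process convention; closing a region
  that (after dilation) touches the border band is therefore not
  shape-preserving there.  Envelope targets sit well inside the frame, so
  this does not affect the pipeline;
- dilation writes only over background (0), never over other labels; erosion
  clears a labelled pixel iff any background pixel falls inside its element.

Closing (dilate then erode with the identical element) is extensive and
idempotent and fills holes smaller than the element; it is the optional
post-processing applied to each grown region (to the local region, before
merging into the global matrix).

## Envelope

External contours are computed from first principles: a foreground pixel is
an external boundary pixel iff it is 8-adjacent to the background region that
is 4-connected to the (padded) image border.  This is equivalent to external
border following and excludes interior hole boundaries by construction.

The upper envelope scan restarts the row index at 0 for each column, skips
leading background, stores the first maximal vertical run of contour pixels
and then abandons the column.  Keeping the whole run (not only its topmost
pixel) preserves vertical contour segments that genuinely belong to the
outer surface; a consequence is that a filled rectangle's envelope includes
the vertical runs of its two outermost columns in addition to its top edge.
The scan guards use `i < h − 1`, so a run confined to the last image row is
never recorded — kept as specified, and irrelevant in practice because the
surface never sits on the bottom image row.

## Reconstruction

Pixel (u = column, v = row, 0-based, origin top-left, pixel centres) maps to
world mm as the first three components of `P · C · (u, v, 0, 1)ᵀ`.  The
calibration `C` (including the mm/pixel scale) and the temporal latency are
*inputs*: estimating them is a calibration problem outside this package.

Frame–pose pairing is nearest-neighbour in time after adding the fixed
latency; pose interpolation is deliberately not attempted (readings are
paired directly).  Pairs with residual gap above `max_gap` (default one frame
period, 1/33 s) are dropped with a warning; dropping *all* frames is an
error.

Voxel compounding is optional and not on the evaluation path (the evaluation
uses the raw masked cloud).  The collision rule is maximum intensity,
preserving the bright surface; last-write-wins is available behind a flag.
Default voxel size 0.1 mm, a parameter rather than a claim about any
particular scanner.

## Alignment and statistics

The similarity fit (rotation + uniform scale + translation) is the
closed-form least-squares solution via SVD of the centred cross-covariance
with a determinant correction for properness and the variance-normalised
scale.  Configurations whose centred source points have rank < 2 (collinear
or coincident) are rejected: the rotation is under-determined.

Scaled ICP: per iteration, transform the cloud, find for each point the
exact nearest point on the reference surface, re-estimate the full similarity
from the original cloud to those footpoints, and repeat until the RMS
improves by less than `tol` (default 1e-6 mm) or `max_iter` (default 100) is
reached, in which case the report is flagged non-converged rather than
raising.  Both half-steps are exact minimisers, so the per-iteration RMS
sequence (recorded in the report) is non-increasing.  `with_scale=False`
fixes s = 1 for a rigid refinement.

Point-to-mesh distances are exact point–triangle distances: for each
point–triangle pair the closest point is the minimum over the in-plane
projection (when its barycentric coordinates are inside) and the three
clamped edge footpoints; pairs are evaluated in memory-bounded chunks over
the full triangle set.  Signed distances take the sign from the nearest
triangle's outward face normal (positive outside), which is what makes the
near-zero mean distances of an unbiased reconstruction meaningful; unsigned
mode is a flag.

Statistics over the distances d_i: mean; sample standard deviation
(n − 1 denominator — the points are a sample of the surface); RMS = √(Σd²/n),
so rms² = mean(d²) exactly; and the fractions within mean ± 2·std and
± 3·std as a normality check (≈95.4%/99.7% for Gaussian errors).  No outlier
rejection by default — all points are reported; an optional maximum-distance
cutoff exists.  The landmark scale factor is defined as
true_length / measured_length (a 15 mm bar measuring 13.939 units gives
1.0761 mm/unit).

Rough alignment takes its ≥3 correspondences from a landmarks CSV;
interactive point picking is out of scope.

## Synthetic phantom and simulator

The phantom is a concatenation of watertight primitives — an annular tube
("dental arch" stand-in), a rectangular block, and a 15 mm × 3 mm × 3 mm
landmark bar — laid out along the sweep axis; it is a geometric stand-in, not
any particular CAD model.  Sweep poses run along a straight line at
33 frames/s, by default ~500 frames per sweep (the per-scan range of a real
acquisition is roughly 450–580), with optional out-and-back travel.  Jitter
defaults (0.2 mm positional, 0.5° rotational, Gaussian per frame) model hand
wobble that the pose sensor records *faithfully* — pose measurement error
(~tens of µm for a CMM arm) is not simulated, so jitter does not degrade the
reconstruction, it only bends the sweep.

Frame rendering intersects the image plane with the mesh, takes the topmost
intersection per column (interpolated at the column's exact lateral
coordinate, so for planar facets the ground-truth point lies on the mesh up
to the half-pixel row rounding) and synthesises: background level,
exponential attenuation below the surface (per-mm coefficient), a
Gaussian-profile bright band (peak 200, σ = 2 px) along the surface, and
additive Gaussian speckle (σ = 5, matching the T ≈ 15 = 3σ threshold
rationale), clipped to [0, 255].  This is *not* physically accurate
ultrasound (no ray tracing, reflection coefficients or refraction;
multiplicative speckle is out of scope): passing tests therefore demonstrate
the geometric and statistical correctness of the pipeline on data with known
ground truth, not robustness to real acoustic artifacts.

Default image geometry (512×512 at 0.05 mm/pixel, probe 10 mm above the
phantom) is a parameter set, not a claim about any scanner; tests and the
acceptance script use scaled-down sweeps (40 frames, 160×160 at 0.1 mm/pixel
noiseless; 8–10 frames at 128×128 noisy; 2 500-point clouds for ICP
recovery) chosen so the full validation runs in about a minute while leaving
every tolerance comfortably resolved.

All randomness flows through `numpy.random.default_rng` with seeds carried in
the specs and recorded in the dataset manifest; frames, masks and pose CSVs
are byte-stable across reruns.

## Known limitations

- The safety-border morphology and the `i < h − 1` envelope scan bound are
  literal conventions; both differ from common library behaviour near image
  edges (documented above).
- Nearest-reading pose pairing (no interpolation) adds up to half a frame
  period of pose error under fast probe motion; irrelevant for the simulated
  linear sweeps.
- ICP with scale against a surface can converge to a slightly biased scale
  when the cloud covers the surface unevenly; the recovery experiment bounds
  this at well under 1% for phantom-like geometry.
- DICOM input is not implemented; frames are 8-bit PNG/TIFF.
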