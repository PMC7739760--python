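# Methods

This note documents the models, conventions, numerical choices, and
known limitations behind `mocapkit`. It is the package's own account of
its science; every empirical number quoted here is computed by the test
suite or by `scripts/acceptance.py`, nothing is asserted from memory.

## Problem setting

A multi-camera markerless motion-capture rig records a single subject
with several synchronized video cameras. A per-frame 2D pose estimator
(BODY_25 layout: 25 body landmarks, each with pixel coordinates and a
confidence in [0, 1]) runs independently on every frame of every
camera. The pipeline turns those per-camera 2D detections into 3D joint
trajectories in a world frame (X lateral/medial, Y anterior/posterior,
Z inferior/superior, mm) and quantifies their accuracy against
marker-based optical capture, the field's reference standard.

Because the estimator treats frames independently, its failures are
temporally uncorrelated: homologous left/right landmarks are sometimes
exchanged, occasional detections land on background objects, and some
landmarks are simply missed. The cleaning stage exists to repair
exactly these modes.

## Camera model and calibration

Each camera is the classic 11-parameter direct linear transformation
(DLT): a 3x4 projective matrix with its bottom-right element fixed to
1, estimated from >= 6 surveyed control points by inhomogeneous linear
least squares (two observation equations per point). No lens-distortion
terms are modelled; this is a stated limitation, acceptable at the
working distances and fields of view of a camera-ring capture volume.

Numerics: world and image coordinates are centred and isotropically
scaled before the solve (RMS radii sqrt(3) and sqrt(2) respectively)
and the similarity transforms folded back afterwards; this keeps the
design matrix well conditioned at mm/pixel scales. Control points are
declared coplanar — a degenerate configuration for the 11-parameter
model — when the smallest singular value of their centred coordinates
is below 1e-6 of the largest. On noiseless synthetic data calibration
recovers generating coefficients to ~1e-13 relative.

## Triangulation

Each keypoint in each frame is triangulated from the cameras whose
detection confidence passes a gate (default 0.1 — drops near-zero junk
detections while keeping plausible ones). The solve stacks the DLT
back-projection equations, two per camera, with the unknowns (X, Y, Z).

The algebraic residual of each equation equals the reprojection error
multiplied by that camera's projective denominator (roughly, relative
depth). Left uncorrected, this implicitly over-weights far cameras; on
the default ring the plain algebraic solution sits ~2 mm from the
geometric optimum at 2 px noise. The solve therefore rescales each
camera's equations by its current denominator estimate and repeats
(two reweighting passes, each still a linear solve), after which it
agrees with a brute-force reprojection-error minimizer to ~0.02 mm —
far below the noise floor. Confidence weighting (each camera's
equations scaled by its confidence) is on by default; with equal
confidences it reproduces the unweighted solution exactly.

A frame-level robustness option iteratively removes the camera with the
largest reprojection residual while it exceeds a threshold (default
20 px at 1920 px image width, scaled with resolution) and at least two
cameras remain. Keypoints seen by fewer than two gated cameras are
marked invalid rather than raising.

## Synchronization

Streams are aligned on a shared light event whose frame index is an
input per camera (the event is identified manually upstream; automatic
detection is out of scope). Alignment is integer-frame: streams are
trimmed so event indices coincide and lengths are equal (maximum common
span). The residual sub-frame offset — up to half a frame period — is
an irreducible comparison error of the method and shows up mostly along
the movement direction.

Marker-based reference data recorded at 200 Hz is brought to the
markerless rate by cubic-spline interpolation (not-a-knot boundaries)
evaluated at the destination timestamps over the common support; no
extrapolation, and downsampling only.

## Cleaning

**Left-right swap correction** operates on the triangulated 3D
trajectories over nine homologous pairs (shoulders, elbows, wrists,
hips, knees, ankles, big toes, small toes, heels). In time order, a
pair's labels are exchanged whenever that strictly reduces the summed
displacement of both members from their last valid positions.
Continuity alone determines labels only up to one global flip per pair
(if the very first frame is swapped, the wrong labelling looks
continuous ever after), so a majority vote follows: a pair that the
greedy pass swapped on more than half of its decided frames is flipped
wholesale. The assumption is that the estimator labels correctly more
often than not. The operation permutes labels only — the multiset of
positions per frame is untouched — and is idempotent. At 10% injected
swap probability on the walking archetype it undoes 100% of injected
swap frames over 100 seeds (`swap_frames_undone_pct`).

**Temporal-outlier flagging** marks a valid frame when its displacement
from the last accepted frame exceeds `vmax` mm per elapsed frame *and*
skipping at most a few frames (default 3) restores continuity. A
sustained step never satisfies the second condition and is kept as
signal. Default `vmax` is 40 mm/frame at 120 Hz, scaled inversely with
the frame period.

**Gap interpolation** fills interior invalid runs up to 24 frames with
a cubic spline through the valid samples (linear when fewer than four
valid samples exist); leading/trailing invalid frames stay invalid and
oversized gaps are reported unfilled.

**Low-pass filtering** is the biomechanics-conventional zero-lag
fourth-order Butterworth: a second-order filter run forward then
backward. The design cutoff is pre-warped by 1/(sqrt(2)-1)^(1/4)
~ 1.2465 so the dual-pass -3 dB point lands at the requested cutoff;
when that correction would push the design cutoff past Nyquist (only
reachable for probe cutoffs near the top of the residual-analysis
grid) it is clamped at 0.995 x Nyquist. Reflective (odd) padding of
three settling spans suppresses edge transients. A user cutoff at or
above Nyquist raises before any computation.

**Cutoff selection** follows Winter's residual analysis: for candidate
cutoffs fc (default grid 0.5 Hz steps from 0.5 to 0.9 x Nyquist) the
residual R(fc) is the RMS raw-minus-filtered difference; a straight
line fitted to R over the high-frequency band (default the [0.6, 0.9]
fraction of Nyquist) and extrapolated to fc = 0 estimates the noise
amplitude a; the selected cutoff is the smallest fc with R(fc) <= a,
or the largest candidate when the residual never reaches the noise line
(noise-free data, where heavy smoothing would only distort). The
selection is scale-invariant. On the walking archetype plus 2 mm noise
the selected cutoffs on movement-direction components land at 2-3 Hz;
note the archetype's lateral axis is a single slow sway harmonic, for
which the method correctly selects ~1.5 Hz — smooth synthetic motion
concentrates at lower frequencies than real human movement, whose
empirical full-HD range is roughly 5-8 Hz.

When cleaning a whole trajectory, the cutoff is selected per
keypoint-axis on series with at least 100 valid samples and the median
is applied everywhere — one cutoff per trajectory, as is conventional.

## Marker-based reference

Joint centres: elbow, wrist, knee, ankle are midpoints of their
lateral/medial marker pairs; shoulders are midpoints of
anterior/posterior pairs; hip joint centres use the Harrington
regression in an explicit pelvis frame (origin mid-ASIS, mediolateral
axis left-to-right ASIS, anterior axis from mid-PSIS toward mid-ASIS
orthogonalized, superior axis completing the right-handed triad):

    AP offset = -0.24 PD - 9.9 mm
    IS offset = -0.30 PW - 10.9 mm
    ML offset = +/-(0.33 PW + 7.3) mm

with PW the inter-ASIS distance and PD the mid-ASIS-to-mid-PSIS
distance. The coefficients are pinned in one constants table and
guarded by symmetry, magnitude (PW = 240, PD = 120 gives -38.7, -82.9,
+/-86.5 mm), and rigid-transformation-equivariance tests. Pelvis-frame
conventions vary between labs; this one is stated so results are
reproducible even where it differs from another implementation's
unstated choice. Marker series are low-pass filtered (residual-analysis
cutoff unless fixed) before joint centres are derived.

## Evaluation

The accuracy statistic is the mean absolute error between the
marker-based and markerless position series per joint, world axis,
task, and camera condition, over task-specific analysis windows whose
event boundaries (heel contacts, toe-off, arm-swing end) are inputs.
Windows must be gap-free after cleaning; by default the six right-side
joints are compared (keypoints 2, 3, 4, 9, 10, 11). Threshold summaries
report the percentage of cells strictly below 20 and 30 mm and strictly
above 40 mm. A packaged survey of 108 published MAE values from a
five-camera validation experiment exercises the summary on real
numbers: 47.2% < 20 mm, 80.6% < 30 mm, 10.2% > 40 mm.

## Synthetic scenes

The simulator generates everything the pipeline consumes:

- **Skeleton archetypes** — walk (periodic sagittal limb oscillation
  plus constant-velocity translation and small sway), jump (squat,
  extension, flight of the pelvis vertical profile with coupled limb
  flexion), throw (rapid unilateral arm rotation out of the sagittal
  plane). All segments are fixed-length vectors rotated per frame, so
  inter-keypoint distances are constant to machine precision. The
  motion is an analytic function of time, which is also how the 200 Hz
  marker reference is produced — by re-evaluating the same motion at
  the marker rate rather than resampling, avoiding interpolation
  artifacts in ground truth.
- **Camera ring** — n cameras (default 5) at 4 m radius and alternating
  heights, pinhole intrinsics (focal 0.9 x image width) with look-at
  extrinsics, converted exactly to DLT coefficients. Twelve control
  points on four calibration-pole placements x three heights; four
  placements rather than two because two vertical poles span only a
  plane, which the calibration module itself (correctly) rejects as
  degenerate.
- **Observation rendering** — exact projections plus Gaussian pixel
  noise (default sigma 2 px), then per-camera corruptions: label swaps
  per homologous pair per frame (`swap_prob`), gross outliers relocated
  uniformly in the image with corrupted-grade confidence
  (`outlier_prob`), and misses zeroed out (`miss_prob`). Confidences
  are Beta(8, 2) for clean and Beta(2, 4) for corrupted detections — an
  invented, stated model that gives confidence gating something real to
  do. Every corruption is logged exactly; applying the logged inverses
  restores the clean observations bit-for-bit.
- **Staggered starts** — each camera drops a random number of leading
  frames (up to 8) and the sync table records the event frame per
  camera, so alignment is exercised end to end.

What the simulator does *not* model: soft-tissue/skin artifact of the
marker reference, correlated estimator errors across frames or cameras,
lens distortion, rolling shutter, lighting. Passing tests therefore
demonstrate the pipeline's algorithmic correctness under its own
stated noise model, not field accuracy on real video.

## Problem sizes and defaults

Tests and the acceptance script use 1.5-4 s trials at 120 Hz with five
cameras — large enough for every statistic they assert (e.g. >= 10^4
pair-frames for corruption-rate checks, 100 seeds for swap-correction
efficacy, 100 instances for the triangulation-oracle bound), and the
full pipeline on these sizes completes in seconds.

End-to-end at study-like settings (5 cameras, 1920x1080, 120 Hz,
sigma = 2 px), every walking-trial MAE cell computed by the acceptance
script is below 4 mm; with zero noise, below 0.01 mm. Real recordings
carry estimator biases and reference-side artifacts the simulator does
not reproduce, which is why published values on real data are an order
of magnitude larger.

## Known limitations

- No lens distortion or bundle adjustment; calibration quality is
  bounded by the plain DLT model.
- Swap correction's majority vote assumes swaps are a minority per
  pair; a pair swapped in more than half its frames would be locked
  inverted.
- Outlier flagging with default lookahead misses spike runs longer
  than three frames (they are treated as signal).
- Multi-person scenes are resolved to a single subject by
  continuity-then-confidence selection; genuine multi-person tracking
  is out of scope.
- Analysis windows are inputs; no automatic gait-event detection.
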