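# Methods

## Contact model and its assumptions

Contact is decided point-wise between a hand-mesh vertex set and a
forearm point cloud with outward unit normals. A hand vertex is
*underneath* the skin when the vector from its nearest arm point to the
vertex has non-positive dot product with that arm point's normal; the
boundary case (dot product exactly zero) counts as contact. The frame
flag is existential — one penetrating vertex suffices. A universal
reading (all vertices underneath) would essentially never fire for a
full hand mesh, since most of the hand is always in the air.

The model assumes (i) the arm cloud is dense relative to the hand's
contact footprint, so nearest-point assignment approximates the true
surface projection; (ii) normals point to the camera side, which is the
outward skin side for a surface scanned from one viewpoint; and (iii)
the arm is rigid over a frame — the cloud is extracted pre-contact and
frozen, so real skin deformation appears as hand-vertex penetration, not
as surface motion.

**Indentation depth** is half the mean vertex-to-nearest-point distance
over contacted vertices, in mm. The half scale compensates for the
connecting segment not being perpendicular to the surface; it is a
convention, not a calibrated skin-mechanics model, so depth is
meaningful as a relative signal (monotone in true indentation) rather
than an absolute deflection.

**Contact area** assigns each *distinct* contacted arm point (the set of
nearest arm points of contacted hand vertices, duplicates counted once)
a disc of radius equal to the cloud's mean nearest-neighbor spacing
$\bar{l}$, with disc constant 3: $A = 3 N_C \bar{l}^2$ (cm²). Counting
contacted hand vertices instead is available via `count="hand"`; the
arm-point count is the default because the area lives on the arm
surface.

*Calibration regime of the disc model.* $3\bar{l}^2$ equals the true
per-point surface area only when $\bar{l} \approx$ (sampling pitch)
$/\sqrt{3}$. That holds for irregular, sensor-like clouds — e.g. a
0.5 mm lattice with Gaussian lateral scatter of ~0.4 pitch, where the
sphere-into-plane test recovers the analytic contact-disc area
$\pi(2R\delta-\delta^2)$ within a few percent. On a perfectly regular
grid $\bar{l}$ equals the pitch and the unit discs overlap threefold, so
the measure runs ~3× high; on a Poisson-random cloud it runs ~25% low.
The factor is constant for a given cloud, so within-session comparisons
and classifications are unaffected; absolute areas should be interpreted
with the cloud's regularity in mind. The synthetic forearm is a regular
grid, so its absolute areas carry the ~3× factor; tests against it use
orderings and ratios, never absolute footprint equality.

## Kinematics

The arm coordinate is built from a vertical unit normal (from a
horizontal support surface or the top of the forearm) and the camera
y-axis: longitudinal = unit projection of camera-y onto the plane
perpendicular to vertical (the forearm is recorded parallel to the image
y-axis), lateral = longitudinal × vertical (right-handed). Degenerate
projections (camera-y within 1e-8 of vertical) raise an error.

Velocity is the raw backward difference of the tracked reference joint —
the middle metacarpophalangeal joint, or a hand marker when only that is
tracked — using *measured* timestamp differences, not the nominal frame
period; no smoothing is applied. The first frame's velocity is reported
as 0 and flagged invalid in a `velocity_valid` mask rather than dropped,
keeping all channels aligned with the contact flags. Per-trial velocity
means are taken over contact frames with valid velocities (a switch
allows all-frame means). Sign conventions: positive longitudinal =
elbow→wrist, positive vertical = upward.

Duration is exactly (number of in-contact frames) / camera rate; the
nominal rate (default 30 Hz) is used only here.

## Forearm segmentation

Crop → voxel downsample (the survivor per voxel is the point closest to
the voxel centre, so coordinates are preserved and the operation is
idempotent) → background removal → region growing → cluster selection.

- Plane background: largest-consensus plane by random 3-point sampling,
  1000 iterations, 5 mm inlier threshold (defaults; the algorithm family
  is standard, the constants are ours). If the best plane supports
  < 10% of the points the scene is returned unchanged with a warning.
- Color background: HSV thresholding of a monochromatic holder. HSV
  bounds are lighting-dependent and must be tuned per scene; defaults
  span typical green.
- Region growing: k = 30 nearest neighbors, neighbors admitted within
  3× the cloud's mean nearest-neighbor spacing, normal deviation below a
  25° smoothness threshold (large enough that the forearm's curvature
  stays one cluster); clusters under 50 points discarded, returned
  largest-first. The arm cluster is the largest by default, or the one
  nearest the color marker.
- Marker tracking is done in 3D on the colored cloud (centroid of points
  in the marker's HSV range) rather than in the 2D image with a depth
  lookup, which would require camera intrinsics; the output contract —
  a 3D marker position driving a rigid translation of the frozen arm
  cloud — is the same.

## Synthetic gestures: what they emulate, and what they do not

The generator stands in for the depth camera and human subjects: a
half-cylindrical forearm (default R = 4 cm, L = 25 cm, 2 mm grid) and a
rigid vertex patch conformal to the arm surface, sized to the gesture's
typical footprint — fingertip ≈ 2 cm², finger pad ≈ 10 cm², full hand
≈ 30 cm². Defaults per gesture: stroke = finger pad sweeping
longitudinally at 10 cm/s (the typical social-stroking speed) with 3 mm
indentation; tap = fingertip dipping vertically at 3 Hz to 3 mm, in the
air roughly two-thirds of each cycle; hold = full hand static at 3 mm;
shake = full hand with band-limited random tangential velocity of 8 cm/s
RMS and a small vertical wobble, contact maintained. Sampling is fixed
at 30 Hz; taps approach the Nyquist limit deliberately, reproducing the
under-sampling that truncates measured tap depth in real recordings.
Batches (`make_trial_batch`) perturb speed, indentation, repetition rate
and duration by ±20% per trial to emulate human variability across
repeats.

Stroke sweeps last an integer number of frames (15 at 30 Hz), so
triangle-wave turnarounds coincide with sample instants and raw finite
differences recover the programmed speed exactly in the noise-free case.

Tracking noise is modelled as *temporally smoothed* rigid jitter:
Gaussian-filtered white noise (σ ≈ 3 frames ≈ 0.1 s) scaled to the
requested positional SD (default 0.5 mm), applied identically to all
hand vertices and the joint per frame. This matches the low-frequency
drift of marker/joint tracks; per-frame white noise of the same SD would
put ~4 cm/s of noise on finite-difference velocities at 30 Hz, which no
unsmoothed pipeline could remove and which real trackers do not exhibit
at that magnitude.

What the generator does **not** emulate: skin deformation (the arm is
rigid), articulated hand pose (the footprint patch is rigid — posed hand
meshes remain an accepted input format), occlusion, RGB imagery,
per-pixel depth noise, and contact force/pressure (unavailable to the
method by construction). Passing tests therefore validate the geometry,
kinematics and statistics of the pipeline, not hand-tracking quality or
skin mechanics on real data.

## Statistics and classification

- Per-trial summaries: contact-frame means of $V_{abs}$, $|V_{lg}|$,
  $|V_{lt}|$, $|V_{vt}|$ (signed channels as absolute values), area,
  depth, plus duration. Zero-contact trials give an all-zero summary
  with a warning.
- Feature set per channel: mean, absolute mean, max, min, quartiles,
  SD, linear-trend slope, skewness, histogram entropy, energy,
  autocorrelations at lags 1–5, partial autocorrelations at lags 1–3,
  leading five Fourier amplitudes, spectrum mean/variance/skew, and
  Haar-wavelet level energies. Non-finite values (degenerate statistics
  of constant channels) are reported as 0, so tables have no missing
  entries; naming is `channel__feature`, deterministic across runs.
- Relevance selection: per-feature Kruskal–Wallis test against the class
  label (rank-based, distribution-free; constant features get p = 1),
  then Benjamini–Hochberg step-up at q = 0.05.
- Classification: random forest, 500 trees, default scikit-learn
  settings otherwise, on a stratified 75/25 split (stratification
  guarantees every class appears in training). Time-series inputs are
  linearly resampled to 100 points per channel and concatenated —
  trials have unequal lengths and a fixed-length design matrix is
  required.
- Permutation importance: per repetition, refit on a fresh split, then
  permute each attribute's columns (grouped by the attribute prefix) in
  the test set; importance = mean accuracy drop over 10 permutations,
  averaged over 100 repetitions; per-repetition values are retained for
  plotting.
- Gesture comparisons: ordinary two-sample Mann–Whitney U on per-trial
  means (the gesture groups are unpaired — a "paired" variant is not
  applicable here), exact for n ≤ 20 without ties, tie-corrected normal
  approximation otherwise, annotated at 0.05/0.01/0.001/0.0001.

## Cross-device validation utilities

Reference series are linearly interpolated onto the camera timestamps
(boolean channels by nearest neighbor); out-of-range targets hold the
edge value with a warning, matching how short boundary mismatches occur
between devices. DTW uses symmetric unit steps, absolute-difference
local cost and no window constraint; matched errors are summarized by
mean (median also reported, since the right summary is a judgement
call).

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data
at desk scale: the default forearm has ~8000 points, footprint patches
50–800 vertices, trials ~120 frames, classification batches 160 trials
(40 per gesture), five batch seeds for the headline accuracy. Nearest-
neighbor search is exact (k-d tree), so oracle comparisons against an
exhaustive O(N²) scan match index-for-index. Normal estimation uses
k-NN PCA (k = 30 default) with normals flipped toward the viewpoint;
collinear neighborhoods fall back to the best-fit direction with a
warning. No-contact frames report depth = 0 and area = 0 (not NaN) so
series stay rectangular; the contact flag disambiguates true zeros.

## Known limitations

- Absolute contact area depends on the cloud's sampling regularity (see
  the disc-model calibration note above).
- Depth is a relative indicator (half-distance convention, no skin
  model).
- Fast taps are under-sampled at 30 Hz; measured tap depth and duration
  are biased low, as in real recordings.
- The segmentation HSV defaults are placeholders; real scenes need
  per-scene tuning.
- Classification numbers on synthetic gestures reflect the generator's
  separability (clean footprints and kinematic laws yield near-perfect
  accuracy), and are an upper bound on what heterogeneous human data
  would give.
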