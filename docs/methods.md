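# Methods

This note records the models behind each stage of the pipeline, the
defaults and why they were chosen, and what the synthetic tests do and
do not demonstrate about the real instrument.

## Coordinate model and calibration

Wells are indexed (row, col) with A1 at the top left — the well the
operator centers and zeroes first — and reduced to grid fractions
u = col/(n_cols−1), v = row/(n_rows−1) in the unit square (a degenerate
single-row or single-column axis maps to 0).  Physical well pitches
(9.0 mm for 96-well, per the standard microplate footprint) are carried
on `PlateSpec` for documentation but never drive the stage: positioning
comes entirely from the calibration, so a pitch error cannot corrupt a
scan.

Each machine axis is modeled as the tensor-product linear surface
f(u,v) = k0 + k1·u + k2·v + k3·u·v.  This is the minimal model exactly
determined by four corner measurements per axis (four coefficients,
four data points, closed form), it reduces to the three-point plane
exactly when the fourth corner is coplanar (k3 = 0), and its warp term
absorbs the leading nonlinearity of a loose-tolerance stage: a
plate-holder/axis system that is rotated, tilted *and* twisted.  It
interpolates, rather than fits, the corners — corner measurement error
propagates directly, which matches how the instrument is used: the
operator re-centers until each corner drop looks right, so the corners
are the most trusted data available.

The planar model is kept as a diagnostic.  Its error against the
bilinear surface is k3·u·v, largest at the far-corner well (|k3|) and
|k3|/4 at plate center; the `calibrate` report compares the z component
against a focus tolerance (default 0.15 mm, one z-step) to show whether
the curved correction matters for a given plate.

Soft travel limits (x ∈ [−5, 160], y ∈ [−110, 5], z ∈ [−10, 10] mm)
only warn: over-driving this class of stage is noisy but not
destructive, and hard limits belong in the firmware, not here.

## Scan planning

Defaults encode the 2 µl-drop protocol: n_z = 5 images per well spaced
dz = 0.15 mm, a 0.1 s settle dwell after every move, a 0.5 s write
dwell per image (0.4–0.6 s is the workable range for SD-card cameras —
shorter and frames get skipped), and one sentinel image per well.

Design choices where the protocol leaves room:

- **Stack centering.**  The z-stack is centered on the calibrated focus
  (levels z0 ± dz·(i − (n_z−1)/2), emitted top to bottom).  Capturing a
  stack exists precisely to tolerate focus-prediction error; centering
  tolerates it symmetrically, a one-sided stack would not.
- **Sentinel position and height.**  The sentinel is captured *last*,
  1.0 mm above the stack top, so it terminates each well's run of
  images and a simple period of n_z+1 holds when nothing is missing.
  The 1.0 mm default is ≫ 3·dz; `ScanConfig` warns if a custom offset
  could leave the sentinel in focus.
- **Relay pulse.**  0.2 s relay closure per trigger — long enough for
  any debounced shutter input, configurable.
- **Dialect.**  Lowercase mnemonics, 3-decimal fixed-point coordinates
  (0.001 mm, below the stage's mechanical resolution), LF endings.
  GRBL is case-insensitive; fixing the dialect makes rendered programs
  byte-reproducible and diffable.  `parse_gcode` inverts `render_gcode`
  on this subset, which the tests use for round-trip checks.
- **Scan order.**  Row-serpentine by default (minimizes travel;
  consecutive wells are always one grid step apart); row-major is
  available.  Segmentation must be told the same order, since well
  labels are assigned by replaying it.

## Stack segmentation

Segmentation never decodes pixels.  A defocused frame has little
high-frequency content, so at fixed JPEG quality it compresses to a
markedly smaller file; the sentinel is defocused far beyond anything in
the data stack, making its size a reliable boundary marker.  This keeps
segmentation O(n) over file metadata.

Two stages:

1. **Candidate detection.**  An image is a sentinel candidate iff its
   size is below `rel_threshold` (default 0.75) times the median size
   of its up-to-(n_z+1) nearest neighbors, already-flagged candidates
   excluded; the exclusion is applied by a growing fixpoint iteration
   so adjacent small files cannot mask each other.  The 0.75 default
   sits between the generator's observed sharp/sentinel size gap
   (≥ 40%) and the size spread among in-focus frames; it is
   configurable because real cameras and quality settings shift both.
   Raising the threshold can only add candidates.
2. **Period reconciliation.**  A dynamic program chooses which
   candidates are true sentinels, requiring 1…n_z data images per
   stack.  Explanations are ranked lexicographically: fewest
   sentinel-less stacks (sentinel frames are rarely lost — they are the
   last and cheapest frame of each well), then smallest total byte size
   of chosen sentinels (true sentinels are the smallest files, which
   stops a merely-blurry data frame from usurping the role), then most
   stacks with exactly n_z data images, then most balanced sizes.  The
   byte-size rank matters in practice: a data frame whose focus landed
   badly can pass the candidate threshold, and stack-count maximization
   alone would sometimes prefer it over the true sentinel.  A segment
   of n_z+1…2·n_z data images — the signature of a lost sentinel — is
   split in two at its interior size minimum, ties toward equal halves.
   On series of ≤ 30 records the DP provably matches exhaustive search
   over all candidate subsets under the same objective (tested).

Stacks are then labeled A1, A2, … by replaying the configured scan
order; a stack-count mismatch flags the manifest rather than failing,
so partial scans remain usable.

## Focus fusion

- **Alignment**: integer-pixel translation only, by FFT
  cross-correlation of standardized frames against the middle image,
  searched within ±20 px.  The settle dwell makes inter-frame drift
  sub-pixel in practice; residual blur in the real instrument comes
  from shutter shake, which no translation can undo.  Shifts at the
  search boundary raise a warning.  Aligned frames are cropped to their
  common overlap.
- **Weights**: local absolute-Laplacian energy (5 px window) plus
  ε = 1e−6, normalized per pixel across the stack.  Contrast only — no
  saturation or exposedness terms, because droplet micrographs are
  near-monochrome and evenly lit, and the goal is depth-of-field
  extension, not exposure fusion.  On featureless regions the ε floor
  degrades the weights to uniform 1/n.
- **Blend**: Laplacian pyramid of each frame mixed level-by-level with
  the Gaussian pyramid of its weight map (re-normalized per level),
  then collapsed and clipped to the input intensity range.  Pyramid
  depth is ⌊log2(min dimension)⌋ − 3, at least 1.  The
  reduce/expand pair is constructed so that collapse exactly inverts
  decomposition, which gives the identity property (fusing n copies of
  an image returns that image) to rounding.  Color frames are blended
  channel-wise with shared luminance weights.

The fused result is as sharp as, but not sharper than, its parents:
tile-averaged Laplacian energy of the fusion stays within ±10% of the
per-tile best input (tested on constructed half-sharp pairs).

## Synthetic acquisitions

The generator emulates what the instrument's camera writes to its SD
card: per well a droplet-like scene (bright rim arcs, 3–7-sided crystal
polygons with dark outlines, precipitate specks, an illumination
gradient, Gaussian sensor noise) rendered at 640×360 by default (the
1080p detector aspect at desk-test scale; the test suite and acceptance
script use 160×120, where the size signature is equally stable and a
24-well acquisition simulates in under a second).

Defocus is sigma = k·|z − z_best| + sigma0 with k = 8 px/mm and
sigma0 = 0.5 px; z_best is drawn per well uniformly within ±dz of the
calibrated plane, the drop-height variability that motivates z-stacks.
Data frames are written at JPEG quality 85 (recorded in the ground
truth); the sentinel at sigma = max(6·k·dz, 8) px, with sigma escalated
at write time if its file is not clearly the smallest of its well —
the generator guarantees the signature it is supposed to model.  Each
data frame is independently dropped with a configurable probability
(sequence numbers keep their gaps, as with a camera that skipped a
write); sentinels are never dropped, matching the reconciliation's
assumption that a lost sentinel is rare.

What passing these tests does **not** show about real data: the
Gaussian-blur defocus model has no optical PSF structure, JPEG sizes of
real droplet images vary with content and lighting more than the
generator's scenes do, vibration and shutter shake are absent, and
sentinel loss is modeled only through the merged-segment path.  The
segmentation threshold and the robustness results should therefore be
read as properties of the algorithm under the stated size-gap
assumption, not as field performance figures.

## Numerical and degenerate-input choices

- Corner interpolation is exact by closed form; tests require ≤ 1e−9 mm
  at the corners.
- A zero-area corner quadrilateral is an error; a non-zero c00 only
  warns (re-zeroing after a power cut may legitimately move the origin).
- 1×N and 1×1 plates are supported via the degenerate-axis convention
  u (or v) = 0.
- Alignment ties in the correlation surface resolve to the
  lexicographically first maximum (deterministic); fusion is
  permutation-invariant to float-sum tolerance.
- Filename sequence numbers are the last integer group in the basename
  (configurable regex); duplicate sequence numbers are an error rather
  than a guess.
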