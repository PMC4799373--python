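# Methods

This note documents the measurement model, the synthetic-scene generator,
and the numerical choices behind `microwound`. Units are micrometres,
hours and micronewtons throughout; pixel coordinates are (row, col),
0-based, pixel-center, with physical position `(x, y) = (col, row) ×
pixel_size`. Calibration (μm/px, h/frame) is always supplied by the user:
TIFF metadata dialects vary too much to be trusted, and keeping calibration
in config makes runs reproducible.

## Segmentation and gap morphometrics

Each tissue frame is thresholded (Otsu per frame by default; a fixed
threshold is available when cross-frame reproducibility matters more than
robustness to drift), morphologically closed (disk radius 2 px) and cleaned
of tissue components below `min_region_area` (64 px). Background regions
that touch the image border are "around" the tissue; the wound is the
largest background component fully enclosed by tissue. When several
comparable holes exist (≥ half the largest), the one nearest the previous
frame's gap centroid wins — a tissue carries a single surgical wound, and
this keeps the series from jumping between transient noise holes.

Shape descriptors of the gap pixel set: area `N·p²`; centroid = mean
pixel-center position; equivalent ellipse from the second central moments
(semi-axes `2√λ` of the covariance eigenvalues, orientation from the
principal eigenvector, reported in (−90°, 90°]); circularity `4πA/P²`.
The perimeter `P` uses the Crofton-formula estimator (4 directions): raw
pixel-edge or marching-squares polygons overestimate smooth boundaries by
~6–8% regardless of resolution, which would bias a perfect disc's
circularity to ~0.89, while the Crofton estimate is asymptotically unbiased.
Tissue width is the median, over the central 50% of occupied columns along
the inter-cantilever axis, of the tissue extent perpendicular to that axis
(an extent, not a solid thickness: internal holes do not reduce it).

A gap is "closed" below 100 μm² (configurable); the assay itself has no
sharper operational definition of closure, and 100 μm² is well below a
single cell's footprint. After the first closed frame, a hole must exceed
twice the closure threshold to count as reopened (it is then flagged);
smaller holes are segmentation noise.

## Closure kinetics

The gap area rises briefly after wounding (the incision relaxes), peaks,
then declines linearly until closure. `detect_widening` takes the argmax of
area over the first 25% of frames (earliest frame on ties). The closure
rate is −slope of an ordinary least-squares fit of area against time from
the widening peak to the last frame above the closure threshold, with the
standard error from the residuals; the fit deliberately excludes the
widening phase, because the "constant rate" property only holds after it.
The fit requires ≥ 4 frames. For a constant series the rate is 0.

Relative closure at a reference time t* is the fraction of peak area closed
by t*, `(A_peak − A(t*)) / A_peak`, divided by the mean of the same
quantity over vehicle-control series (so any series against itself is
exactly 1). Whether published "relative closure rates" normalize closed
fractions or fitted slopes is ambiguous; fraction mode is the default and a
slope-ratio mode is provided. Normalization is within-run; controls are
never pooled across runs. Centroid drift is the maximum distance of any
open-frame centroid from the first open frame's centroid.

## Tracking and directionality

Nuclei are detected as maxima of the scale-normalized Laplacian of
Gaussian (σ = expected nuclear spot size, default 2.5 μm), refined to
sub-pixel position by an intensity-weighted centroid in a ±2σ window, with
detections closer than one σ merged (strongest kept). Linking is greedy
globally-shortest-first between consecutive frames with a hard link-length
cap (default 20 μm per 30-min frame, i.e. 40 μm/h — generous against
fibroblast speeds); unmatched detections start or end tracks and there is
no gap closing. Greedy linking was chosen over global optimal assignment
because at realistic nuclear densities it is equally accurate and trivially
auditable.

The radial migration angle of a track is the angle between its net
displacement over the analysis interval and the unit vector from its start
position toward the gap centroid at the start frame, folded to [0, 180]°:
0° = toward the wound, 90° = tangential, 180° = away. The folding choice
(rather than signed angles) matches how windrose plots of migration are
conventionally read. Windrose histograms default to 20° bins so that both
0° and 90° are bin interiors; a 15° binning would place 90° on a bin edge
and split a purely tangential population across two bins. Location classes
use the track's mean distance to the segmented wound boundary of the same
frame (last open boundary once closed): ≤ 25 μm ⇒ edge, ≥ 100 μm ⇒ distal,
else other. "Maximum speed" is the per-track maximum frame-to-frame speed —
the definition is stated here prominently because averaged or windowed
speed definitions give systematically smaller numbers.

## Tension from cantilever beads

Fluorescent beads embedded in the cantilever caps are tracked by an
iterated (3×) background-subtracted intensity-weighted centroid within a
search window (default ±8 μm) around the previous position; a bead with no
signal above `min_signal` over the window median is flagged lost and
excluded. Deflection per cantilever is the mean over its beads of the
displacement from the post-release rest position, projected onto the
inter-cantilever axis and signed toward the tissue midline. Projection (not
planar magnitude) is the default because off-axis bead jitter is
measurement noise, not load; a magnitude mode is provided for comparison.
Total tension is `F(t) = k·Σ_c δ_c(t)` with the calibrated spring constant
`k` (default 2.67 μN μm⁻¹); the baseline is the mean tension over a
configurable pre-wound window (default the first frame), and normalized
tension divides by it.

## Synthetic scene generator

The generator emulates the assay geometry the pipeline assumes, on a
512-px field at 1.6 μm/px (a 10× EMCCD field of view), 30-min frames for
24 h:

- **Gap dynamics.** Area rises linearly from `initial_gap_area` (default
  30,000 μm²) to `(1+f)`× over the widening phase (f = 0.2, 1 h), then
  declines at `closure_rate` (default 1,344 μm² h⁻¹), clipped at zero. The
  boundary is an ellipse (aspect 1.5, major axis along the
  inter-cantilever axis) times a low-order Fourier roughness whose
  amplitude (8% of radius) decays to zero over the widening phase — the
  fresh rough edge smoothens into an ellipse. Each frame's boundary is
  rescaled so its enclosed area equals the analytic trajectory exactly (to
  quadrature accuracy); rasterized masks match within ~0.5% for gaps
  ≥ 500 px. The centroid never moves.
- **Cells.** Edge cells (25% of 200 by default) seed within 2–22 μm of the
  boundary and step exactly perpendicular to the local radius
  (persistent per-cell direction, 10 μm h⁻¹); distal cells seed
  110–160 μm outside the boundary and step radially inward (5 μm h⁻¹,
  stopping at the boundary). Isotropic Gaussian positional noise
  (2 μm h⁻¹ per coordinate) is added, and a soft volume exclusion keeps
  nuclear centers ≥ 12 μm apart — real nuclei are ~10 μm and do not
  interpenetrate; without exclusion the random walks drift into sub-
  resolution encounters no tracker (and no microscope) could separate.
  Cells neither divide nor die (closure is proliferation-independent in
  this assay).
- **Tension and beads.** The tension profile is piecewise linear through
  (0 h, baseline 12 μN) → (first post-wound frame, 6 μN) → (10 h, 16 μN)
  → (24 h, 11 μN): collapse on wounding, contraction peak near 10 h,
  plateau slightly below baseline. The literature for this assay reports
  the profile shape but not absolute values in text, so the magnitudes
  were fixed once at values typical for fibroblast microtissues on
  k ≈ 2.67 μN μm⁻¹ cantilevers. Tension splits equally across the two
  cantilevers; each cap (and its 4 beads, rigidly) deflects by `F/(2k)`
  toward the midline, so ground-truth deflection × 2k reproduces the
  input tension identically.
- **Rendering.** Tissue = bright band (0.8) between the caps against
  background 0.1, with the gap carved out using 1-px anti-aliased
  coverage; nuclei and beads are Gaussian spots (σ 2.5 / 2.4 μm) on black;
  all channels get additive Gaussian noise (σ 0.08 ≈ 10% of dynamic
  range), clipped at zero. All randomness flows from the single config
  seed through spawned substreams, so identical configs give bit-identical
  stacks.

What the generator does **not** emulate: phase-contrast texture and shading
inside the tissue, uneven illumination, photobleaching, focus drift,
nuclei entering the gap on the fibronectin template, cell division, and
bead-image overlap with tissue signal. Passing recovery tests on these
scenes therefore validates the measurement chain (geometry → segmentation
→ fitting → conversion), not robustness to every real-world imaging
artifact; on real data the fixed-threshold mode, detection threshold and
search radii are the knobs to revisit.

## Free parameters the assay literature does not pin down

Edge-band width (25 μm), tangential/radial speeds (10/5 μm h⁻¹), the
noise level, the net-displacement analysis interval for windroses, and the
per-bead aggregation (mean) are free parameters; each default is exposed in
config and was chosen once as a realistic value, not fitted. The confocal
preprocessing "noise reduction" is implemented as a median filter
(radius exposed) followed by `log(1+x)` — the log form handles zero-valued
pixels — and a max z-projection rescaled to [0, 1].

## Problem sizes

The test suite validates against full-size default scenes (512 px, 49
frames, 200 cells) for the end-to-end criteria, and uses 256-px cell-free
scenes for the many-seed statistical checks (50-seed rate recovery,
10-seed tension RMS); those sizes are stated in the tests and keep the
whole suite under a few minutes without changing any measured conclusion.
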