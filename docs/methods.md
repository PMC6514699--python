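# Methods

This note documents the models, conventions and numerical choices behind
`leafgeom`, and what the synthetic experiments do and do not demonstrate.

## Scene model and coordinate conventions

Images are `(H, W)` or `(H, W, 3)` arrays, origin at the top-left pixel
centre, `x` rightward (columns), `y` downward (rows); all coordinates are
0-based pixel centres.  Binary masks hold exactly {0, 1} with 1 marking
*dark* foreground — the leaf, the black frame and the tick marks on a
light plate.

The calibration plate model: a black rectangular frame of outer size
`width_mm × height_mm` (default 160 × 120 mm) and border thickness
3 mm, printed on a light plate that extends 12 mm beyond the frame.
Tick marks at 1-mm pitch (0.3 mm wide, 2.5 mm long) sit just inside the
upper and left frame borders, separated from the border by a 0.4 mm gap
so they remain separate connected components.  The default frame is
large enough to hold leaves up to ~80 cm²; all plate geometry is a
config input and must match the physical plate in use.

## Pre-processing

* Greyscale: weighted average with BT.601 weights (0.299, 0.587, 0.114),
  configurable.  Output is rounded to uint8.
* Smoothing: Gaussian with reflective borders (mass-conserving);
  `sigma` defaults to 1.0 px.  `sigma = 0` is the identity — the
  degenerate 1 × 1 kernel — and is used wherever pixel-exact masks are
  needed.
* Binarisation: Otsu's between-class-variance criterion on the 8-bit
  histogram, dark class as foreground (`value <= threshold`); a constant
  image raises a degenerate-image error.  A fixed threshold is available
  as a fallback.  Local/adaptive thresholding of the leaf is explicitly
  out of scope.

## Distortion calibration

Corner detection extracts the component with the largest *enclosed*
(hole-filled) area — ranking by enclosed rather than raw pixel area is
what lets the thin frame outrank a large leaf — and simplifies its outer
sub-pixel contour (marching squares) to a quadrilateral with
Douglas–Peucker, starting at a tolerance of 1% of the contour perimeter
and multiplying by 1.5 up to 10% until exactly four vertices remain.
The contour is re-anchored at its farthest-from-centroid point first,
since Douglas–Peucker always keeps its endpoints.  Because blur and
antialiasing round the rasterised corners, each DP vertex is then
refined by fitting total-least-squares lines to the central 76% of the
two adjacent sides and intersecting them; on noiseless renders this
brings corner error below 1 px at every tilt in 0–45° (≈0.2–0.7 px in
practice).  An alternative Hough-line detector (peak pairs of
near-horizontal/near-vertical lines, intersected) is available behind a
config switch; it is coarser (line-accumulator quantisation) but does
not depend on polygon approximation.

The projective transform uses the full 8-degree-of-freedom model with
denominator `Gx + Hy + 1` and scale fixed at λ = 1, solved exactly from
the four corner pairs as an 8 × 8 linear system.  Rectification
inverse-maps every output pixel through the transform and samples the
source bilinearly, so the rectified image (default 10 px/mm) has no
unfilled pixels; the frame's outer corners land exactly on the rectified
image corners.

## Dynamic-reference measurement

The rectified mask is re-extracted into frame and leaf (the two largest
enclosed areas).  The leaf contour is hole-filled before counting, so
lesions and wormholes do not reduce the measured area: interior holes
totalling ~10% of the area change the measurement by under 0.2%.

Pixel conventions: the positive circumscribed rectangle records extreme
pixel coordinates; extents are `max − min` while interior counts use
`max − min + 1` (pixel-area semantics).  The rectangle's physical sides
lie half a pixel outside the extreme pixel centres, so tick-gap
fractions are measured from `min − 0.5` and `max + 0.5`; this keeps the
physical lengths consistent with the interior counts and removes a
systematic one-pixel (−0.1 mm at 10 px/mm) bias.

**Tick reading.**  Tick pixels are isolated in bands just inside the
upper and left frame borders (band geometry derived from the scanned
frame thickness, not from config).  Fragments broken by binarisation are
reconnected by dilating along each ruler's tick direction with a
1 × k / k × 1 element, k = round(49 · image width / 3264), minimum 3 —
the 49-px reference length is calibrated to ~3264-px captures and scales
with resolution.  Two refinements handle low-resolution and strongly
foreshortened captures, where the ~0.3 mm ticks antialias into shallow
intensity dips that a global threshold misses:

* *band-local recovery*: per tick-lane thresholds (90th-percentile light
  level minus 45% of the lane contrast, gated at 40 grey levels) restore
  faint ticks from the rectified greyscale, skipping the 15% of the band
  nearest the frame border where blur smear would bridge neighbours;
* *sub-tick grid fit*: the recovered centroids are snapped to a fitted
  regular grid — pitch from the robust median spacing (majority of
  adjacent spacings within 20%), phase from the circular mean of the
  residuals — which averages centroid noise over the whole ruler and
  fills interior dropouts.

Physical spans are then read as: whole tick spacings between the first
and last tick inside the span (snapped first-to-last distance, which
equals *(n − 1)* spacings on a complete ruler but survives dropouts)
plus the fractional end segments converted at the derived px/mm scale.
An edge within 0.5 px of a tick centre counts that tick with zero
fraction.  If a *complete* ruler fails to cover the span the measurement
raises an out-of-range error; an *incomplete* ruler (dropouts — e.g. the
far half of the left ruler at 45° tilt, which is genuinely unresolvable
at 1600-px capture) falls back to pixel-scale conversion for the
uncovered part, exact in rectified coordinates.

**Area and perimeter.**  `S = S_r · P_t / P_rt` and
`C = C_r · P_c / P_ct` with `S_r = L_r W_r`, `C_r = 2(L_r + W_r)`.
`P_t` is the hole-filled interior count, `P_rt = (Δx+1)(Δy+1)`,
`P_ct = 2(Δx+1) + 2(Δy+1) − 4`.  For `P_c` a raw border-pixel count
would be biased: a digitised disc has ≈ 4√2·r border pixels against a
true circumference of 2π·r, so the perimeter ratio would understate
smooth shapes by ~10% while leaving rectangles exact.  `P_c` is
therefore the length of the leaf's sub-pixel outer contour after
Douglas–Peucker simplification at 1.2 px tolerance, which removes the
rasterisation staircase: accurate to ~0.1% for discs *and* axis-aligned
rectangles (verified against analytic values at r = 300 px), so the
rectangle self-reference property is preserved to <0.2% while curved
perimeters come out unbiased.  The raw 8-connected border count remains
available as `Contour.pixel_count_boundary`.

Length is the x-extent and width the y-extent of the rectangle; the
leaf's elongation axis is assumed parallel to the plate sides.  Rotated
(elongation-aligned) rectangles are out of scope.

## Synthetic scenes

The renderer replaces the physical clamp device and phone camera.  The
camera is a pinhole with fixed focal length (chosen so the plate fills
~72% of the image at the closest bench distance, 230 mm) tilted about
the plate's horizontal centreline, lower half nearer the camera; the
induced plate-to-image homography is exact and attached as ground truth,
together with the true frame-corner positions.  Full 6-DOF pose, lens
distortion and photorealism are out of scope.

Silhouettes are exact polygons (square, rectangle, isosceles triangle —
base 6 cm, height 6 cm, matching the printed area 18.00 cm² and
perimeter 19.4 cm — and discretised circles) or star-convex radial
curves for the leaf templates: heart = offset cardioid (cucumber),
oval = ellipse of aspect 1.4 (soybean), slender = ellipse of aspect 7
(rice), serrated = lobed ellipse of aspect 1.25 with 36 sawtooth teeth
(default amplitude 4%) and three seeded low-order Fourier lobes of
amplitude ≤3% (tomato).  Templates are scaled to a requested area;
attached truth comes from a 2¹⁴-vertex boundary polygon (regular shapes
carry analytic truth).  Scenes are evaluated analytically at a 4×
supersampled grid through the inverse camera homography and
block-averaged, giving sub-pixel edge fidelity; blur, additive Gaussian
noise and an optional leaf-edge shadow band (65% ink, emulating the
positive area bias of thick leaves; off by default) are applied to the
downsampled image.  Camera distances below 235 mm add defocus blur
(+0.5 px sigma below 235, +0.8 below 232.5 — a stated config table, not
physics).  Rendering is bit-deterministic under a fixed seed; seeds
change only noise and serration, never the ground truth of regular
shapes.

Default capture width is 1600 px (phone-native 3264–4608 would be ~4×
slower to render and process; the tick-kernel scaling absorbs the
difference).  The renderer reproduces geometry, edge blur and sensor
noise but not texture, specularity, uneven illumination or curled
leaves, so passing benchmarks demonstrates the geometric correctness of
the pipeline — calibration, scale recovery and the ratio estimators —
not robustness to field imaging conditions.

## Benchmark panels and problem sizes

The reference panels (module `leafgeom.benchmarks`) use the study
conditions: 1600-px captures, 10 px/mm rectification.  The tilt sweep
covers the four regular shapes × tilts {0, 15, 30, 45}° at 240 mm with
blur sigma 1 px, noise sd 2, three noise realisations per cell.  The
leaf panel is 20 seeded silhouettes, 5 per template, at mixed tilts
{0–45}° and distances {235–260} mm with blur 1 px and noise sd 3; areas
are drawn per template from the ranges that physically fit the frame
interior (slender at aspect 7 cannot exceed ~14 cm²; broad templates
range 18–80 cm²).  Unit and property tests use 800–1200-px renders,
where sub-pixel bounds (self-reference < 0.5%, resolution robustness
< 0.5%) hold from ~1200 px upward.

## Known limitations

* The tick rulers become unresolvable under strong foreshortening at low
  capture resolution; the pipeline then leans on the rectified pixel
  scale, whose accuracy is set by corner detection (~0.5 px over a
  ~1400 px frame, i.e. <0.1%).
* Leaves must not touch the frame or tick region; multi-leaf scenes and
  overlapping petioles are unsupported.
* Perimeter of deeply serrated boundaries is resolution-limited: teeth
  below the simplification tolerance (1.2 px) are smoothed away, as with
  any finite-resolution contour method.
* The error model omits illumination gradients and shadows apart from
  the explicit edge-shadow band.
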