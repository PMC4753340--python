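# Methods notes

## Scene model and what the pipeline assumes

The pipeline targets B-mode craniocervical sonograms at roughly the C4
level: inside the operator-chosen ROI the deep cervical flexor (DCF) appears
as a dark band bounded above by its bright superficial fascia and below by
the bright echo caps of (typically three) cervical vertebrae, with acoustic
shadow beneath the bone. It assumes left-dominant anatomy — the leftmost
vertebra, which anchors the measuring key point, lies in the left half of
the ROI; the distance-weighted restoration retry exists for the case where
its echo is so dim that thresholding loses it, and `PipelineConfig.mirror`
flips the convention for right-dominant acquisitions. Every stage is
deterministic; identical input and configuration give bit-identical output.

## Coordinate, rounding and tie conventions

* Pixels are (x = column, y = row), 0-based, y growing downward; ROIs are
  half-open `[x0,x1) × [y0,y1)`.
* All rasterization rounds half-up (`floor(x + 0.5)`), project-wide: DICOM
  rescale, stretch, spline and DDA row values, the ±1 cm column offset.
* Average binarization maps a pixel *equal* to the mean to foreground; the
  noise-rule comparisons are strict (`<`), exactly as the thresholds are
  stated; Otsu tie-breaks to the smallest maximizing threshold (foreground
  is `> T`).
* The key point takes the maximal-x pixel of the leftmost vertebral object,
  ties resolved to the smallest y; "leftmost" ties resolve to the smaller
  bounding-box top.

## Fuzzy sigma binarization

`p_min/p_max` are taken from the image actually passed in — in the pipeline,
the contrast-stretched ROI — and `p_mid` is their midpoint at full precision
(possibly a half-integer; membership decisions are never pre-rounded).
Two wrinkles are worth recording:

* The half-width selection (Step 3) is implemented verbatim as the printed
  nested conditional; a unit test documents that it reduces to
  `min(p_mid_f, p_max_f)` / `min(p_min_f, p_mid_f)` per branch.
* The bright-image compensation (Step 2, `p_mid_f = 255 − p_mid` when
  `p_mid` exceeds the upper three-quarters point) is **dormant** under the
  midpoint definition of `p_mid`: the condition reduces to `0.5 > 0.75`.
  It is kept for fidelity and covered by a test asserting it never fires.
* The membership's upper branch is taken as `u = 1` for `P ≥ p_mid`, the only
  reading consistent with the linear middle branch's denominator.
* A constant image yields `β = 0`; membership degenerates to a step at
  `p_mid` (logged), and the pipeline refuses constant ROIs outright.

## Object-level noise rule

`S(O) < 0.085·S(ROI)` compares object area to ROI *area*; the 8.5% constant
therefore makes survival depend on absolute structure size, which drives the
phantom geometry below. The left-skew clause (`O.left < 0.1·W` and
`Width(O) < 0.5·W`) deliberately spares full-width boundary lines. The same
constants are applied in both the candidate stage and the vertebra stage
(configurable independently of each other only through a shared config; no
evidence suggested different values). One consequence: boundary-line objects
(fascia) legitimately survive into the vertebra stage, so the vertebra chain
additionally rejects objects spanning ≥ 90% of the ROI width
(`vertebra_max_width_frac`) — a compact vertebral body can never be that
wide, while the preserved fascia always is.

## Boundary reconstruction

Natural cubic splines (`S″ = 0` at both end knots, non-uniform knot spacing
solved exactly via `scipy.interpolate.CubicSpline(bc_type="natural")`) fill
missing columns; an independent tridiagonal solve in the test suite pins the
coefficients to 1e−9. Splines never extrapolate: full-width boundaries are
anchored by repeating the first/last known row at the ROI edges before
fitting (`extend_flat`). Across inter-vertebral gaps the echo-top line is
first connected by DDA line rasterization (the vertical case, undefined by
the slope formula, emits all integer rows between the endpoints — a
documented extension). Contour tracing follows the cracks between foreground
and background with a fixed turning rule (foreground on the right), which
yields closed loops visiting exactly the pixels with a 4-adjacent background
neighbor, including one loop per interior hole.

## Measurement conventions

* The upper measurement boundary is the **top of the candidate band** (the
  superficial fascial echo's upper edge); the lower one is the **top of the
  vertebral echo line**. The method's description does not name the upper
  landmark, so the mask-top convention is this package's choice, and the
  phantom defines its "DCF thickness" identically (fascia top → bone-echo
  top) so that truth and measurement refer to the same band.
* The ±1 cm offset uses the x-axis spacing; chord lengths use the y-axis
  spacing, so anisotropic pixels are handled.
* Without calibration (no DICOM `PixelSpacing`, no override) the CLI errors
  unless a pixel offset is accepted, in which case thickness is reported in
  pixels with a warning.
* The distance-weighted restoration multiplies the *grayscale* stretched ROI
  (boosting a 0/255 binary image with a ≥ 1 weight and a 255 clamp would be
  a no-op) and the vertebra stage then re-thresholds once with average
  binarization; if the retry finds nothing the pre-retry objects are kept.

## Phantom: what it emulates, and what it does not

The generator draws, at 0.01 cm/px in an 800×600 raster with a 500×250 ROI:
a bright skin line, dark SCM band with fascia, dark vessel ellipse (all above
the ROI), then the DCF complex — a 22 px superficial fascia arch, the dark
muscle band, three 138×90 px vertebral echo caps whose brightness fades with
depth (185 → ~95), and shadow beneath — followed by unit-mean multiplicative
gamma speckle (relative variance 0.15) and a σ = 1 px Gaussian blur. Key
sizing choices are consequences of the 8.5% noise rule: every structure that
must survive it (fascia band, each echo cap) needs area ≥ 0.085·125000
≈ 10 600 px. The fading cap bottoms create the low-contrast regime the fuzzy
binarizer exists for: a mean-level threshold clips them while the fuzzy cut
(at half the min–mid ramp) does not. The default intensity histogram is
strongly skewed toward zero, as in real craniocervical sonograms.

Not emulated: wave-physics speckle correlation, refraction/reverberation
artifacts, probe-pressure deformation, patient-level anatomical variability,
oblique or curved vertebral arrangements. Passing the phantom batch
therefore demonstrates the pipeline's internal correctness and its behavior
under the modeled contrast/noise conditions, not clinical accuracy.

## Problem sizes used by the checked runs

The acceptance script and the end-to-end tests use 50 phantoms (seeds
base…base+49, thickness truth uniform in 0.6–1.4 cm) for the pipeline
statistics and 20 phantoms for the binarizer comparison; the degradation
trend check uses 6 phantoms at each of three speckle variances
(0.05 / 0.15 / 3.0). These sizes give stable statistics for a deterministic
pipeline while keeping a full run in seconds.

## Known limitations

* The fat-false-positive rule compares an object's bottom row with the
  band's lower line at the object's *centroid column* only; an L-shaped fat
  object with an off-band centroid could be misjudged.
* The candidate band includes the bright boundary structures themselves
  (fascia above, echo caps below), so its pixel precision against the
  muscle-only band is structurally modest; the final mask, trimmed at the
  vertebral echo line, is the precise one.
* With `shift_right` anatomies the restoration weight saturates most of the
  image far from the center (the quadratic distance over a 1000 divisor
  exceeds 2 beyond ~32 px), so the retry is a blunt instrument; it recovers
  the trigger scenario but degrades segmentation quality.
* Multi-frame/color DICOM, cine loops and Doppler are out of scope.
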