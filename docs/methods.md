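# Methods

## Processing model

All segmentation happens in a polar resampling of the frame around the
imaging-catheter center: rows are angle bins (A-lines), columns are
radius bins, radius increasing left to right.  The catheter is assumed
to sit at the polar origin; its center defaults to the image center and
can be overridden per frame, since catheter detection is out of scope.
The polar grid defaults to 360 angle bins (1°) and one radius bin per
pixel (`radial_spacing_mm = pixel_spacing_mm`, default 0.01 mm/px,
consistent with the 10–20 µm resolution of frequency-domain OCT);
resampling is bilinear to avoid nearest-neighbour staircase on the
border.

The pipeline assumes a *star-shaped* lumen with respect to the catheter:
one border radius per angle.  This holds for essentially all native
coronary cross-sections but not for, e.g., dissection flaps.

## Stage-by-stage choices

**Overlay removal.** Burnt-in markers are colored while OCT signal is
achromatic; a pixel is "colored" when its RGB channel spread exceeds 10 %
of full scale.  The tolerance absorbs chroma bleed from lossy sources;
removal is idempotent.

**Catheter removal.** The innermost `ceil((d/2 + margin)/spacing)`
radius bins are blanked in every A-line.  `d` is the physical catheter
diameter: the French gauge at 1 Fr = 1/3 mm, or an explicit value when
the vendor quotes a rounded figure (0.91 mm for the 2.7 Fr Dragonfly).
A diameter of 0 means "no catheter" and removes nothing.  The margin
(default 0.05 mm) covers the sheath's bright reflection just beyond the
nominal radius.

**Despeckling.** 5×5 median filter, then Gaussian smoothing with
σ = 2 bins.  The Gaussian width is a design choice: wide enough to blur
speckle remnants that survive the median, narrow enough that the intima
leading edge moves by at most about one bin.  Both filters replicate the
image edge, which avoids dark halos at the catheter-adjacent border.

**Binarization.** Otsu's between-class-variance maximization over a
256-bin histogram, the standard parameter-free rule for the bimodal
dark-lumen / bright-tissue histogram.  A constant image raises a
degenerate-histogram error (this is the failure path for all-black
frames, which are logged and skipped rather than aborting a pullback).

**Morphological cleanup.** Opening then closing with a flat disk of
radius 5 bins, the disk preserving the circular character of the wall.
The image edge is treated as foreground during erosion and background
during dilation (the convention of the MATLAB-style toolboxes), so wall
segments touching the border are not eaten away.  The open–close
composition is idempotent.  Components smaller than the structuring
element's area (81 px) are discarded afterwards: they cannot be intima
and are, in practice, residual-blood clutter.

**Gap bridging.** Components are ordered top to bottom by their minimal
angle row and consecutive pairs are connected; the angle axis is treated
as cyclic, so the last component is also bridged back to the first (the
vessel is closed; when the wall is already contiguous across the array
seam this adds a degenerate, near-zero bridge).  Candidate endpoints are
the upper component's bottom-left extreme and the lower component's
top-left / top-right extremes; the lower endpoint minimizing Euclidean
distance wins.  The distance is measured in Cartesian millimetres
(converting the polar pixel coordinates), because the 2 mm
guide-wire-vs-bifurcation cutoff is physical: a wedge of width Δθ at
border radius r produces a chord of 2·r·sin(Δθ/2).  Both gap kinds are
bridged — the flag only widens the endpoint refinement (2 rows into the
component for guide-wire-scale gaps, 5 for bifurcations), where each
endpoint is re-anchored at the innermost white pixel a few rows inside
its component to avoid sharp corners.  A straight pixel line between the
refined endpoints is set to foreground.  Bridging only ever adds
foreground.

**Border extraction.** Sobel gradient magnitude on the bridged mask;
per A-line the border is the innermost tissue-side edge position (the
lumen border is by definition the inner boundary of the intima).  Any
A-line without foreground at this point signals a bridging failure and
raises.

**Contour smoothing.** The closed radius signal is convolved cyclically
with Savitzky–Golay weights (window 35, order 2).  Cyclic boundary
handling is the natural choice for a closed outline; smoothing the
radius signal (rather than x/y separately) preserves star-shapedness.
The weights reproduce any quadratic-in-index sequence exactly and
preserve the mean, since they are normalized to sum 1.

**Quantification.** Area by the shoelace formula on the Cartesian
contour.  Diameters are chords through the contour centroid at 180
equally spaced directions (each chord the sum of the two opposite-ray
border distances), which reproduces circle/ellipse closed forms and is
rotation-stable.  Agreement between two measurement series uses the
sign convention "first-listed method minus second"; RD/ARD normalize
each per-frame difference by the larger of the two values; the ICC is
the two-way random-effects, absolute-agreement, single-measure form
(ICC(2,1), computed via pingouin) with the F-based 95% CI; Bland–Altman
limits use the sample (N−1) standard deviation and ±1.96 SD.

## Phantom generator

The generator renders what the segmentation logic actually depends on,
with exact analytic truth:

- lumen border ρ(θ): circle, ellipse in polar form, or a base radius
  with low-order Fourier perturbations (orders 2–3, a few per cent);
- a bright intimal ring (intensity 0.85) of 0.35 mm thickness starting
  exactly at ρ(θ), with an exponential outward decay (length 0.2 mm) so
  thresholding sees a realistic bright-leading-edge profile;
- a catheter ring at the configured physical diameter (default 0.91 mm);
- optionally a guide-wire spot at the border with a zeroed radial shadow
  wedge behind it, a bifurcation wedge erasing the ring, Poisson-placed
  residual-blood blobs near the catheter, and multiplicative
  Rayleigh-mixture speckle (mean 1) on tissue pixels only.

Rendering is deterministic in the spec (including its seed), and the
truth never depends on the noise settings.  Default geometry: 512 px
frames at 0.01 mm/px; suite lumen radii 1.0–1.7 mm, chosen to match
typical coronary lumen diameters of ≈2.5–3 mm; wedges up to 60°;
speckle level 0.3.

What the phantom does *not* model: depth-dependent attenuation and
catheter optics, motion artifacts, stents and strut shadows, plaque
heterogeneity, eccentric catheter positions.  Passing the recovery suite
therefore demonstrates correctness of the geometry, artifact-bridging
and quantification logic under controlled conditions — not clinical
accuracy, which can only be assessed against expert-annotated pullbacks.

## Recovery suite and reported numbers

The standard suite is 24 phantoms (8 each circle/ellipse/Fourier,
three quarters carrying artifact combinations).  `scripts/acceptance.py`
segments the suite and reports group ARD of lumen area (artifact-free
and with artifacts), mean-diameter ARD, maximum border deviation in
radial bins on artifact-free phantoms, and the ICC between recovered
and true areas.  Typical values: area ARD ≈ 0.4 % artifact-free and
≈ 0.9 % with artifacts, border deviation well under one radial bin,
ICC > 0.99.  The internal test thresholds (< 3 % / < 6 % / ≤ 2 bins) are
implementation acceptance bounds, deliberately loose against these
typical values.

The published clinical summary (667 frames, four methods) is shipped as
per-method means only; the raw per-frame data are not deposited, so the
clinical ICC/Bland–Altman figures are not reproducible here.  The
package checks the arithmetic consistency of those means (pairwise mean
differences under first-minus-second subtraction) instead.

## Numerical notes and limitations

- Gap lengths quoted in `GapBridge` use the pre-refinement extreme
  points; through the full pipeline the disk-5 opening rounds component
  corners, which can lengthen a measured gap by ~2–3 radial bins
  relative to the geometric chord.
- The Otsu threshold sits slightly below the intima half-height because
  of the decaying outward tail, biasing the border inward by well under
  one bin on phantoms.
- Multiframe DICOM support covers pixel data, frame count and pixel
  spacing; vendor private tags are ignored.  8-bit storage quantizes
  intensities to 1/255.
- Frames are processed independently; no longitudinal regularization
  along the pullback.
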