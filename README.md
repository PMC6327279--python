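# octlumen

Fully automated lumen segmentation for intracoronary optical coherence
tomography (OCT).

Intravascular OCT produces high-resolution (10–20 µm) cross-sections of
coronary arteries from a catheter pulled back through the vessel.  The
first and most important measurement on every frame is the **lumen**:
the blood-filled channel bounded by the inner edge of the bright intimal
ring.  Manual delineation by core-lab analysts is slow and variable, and
automatic delineation is complicated by ring-shaped catheter reflections,
the guide-wire shadow that cuts a dark wedge through the wall,
bifurcation ostia where the wall is genuinely absent, and speckle from
residually non-diluted blood.  `octlumen` is aimed at researchers who
need per-frame lumen contours and quantitative lumen metrics from raw
pullbacks without excluding difficult frames.

## Method

Each frame is processed in the polar domain around the catheter center,
where the circular wall becomes a straightened band:

1. **Preprocessing** — colored overlay removal, NTSC grayscale
   (`0.299 R + 0.587 G + 0.114 B`), polar transform, removal of the
   catheter ring of known physical diameter (2.7 Fr → 0.91 mm for the
   Dragonfly catheter), 5×5 median filter, Gaussian smoothing, automatic
   (Otsu) thresholding.
2. **Segmentation** — morphological opening and closing with a flat disk
   of radius R = 5 to clean the binary intima mask; boundary tracing of
   every 8-connected component with its eight extreme points; gaps from
   guide-wire shadows and bifurcations are bridged by straight-line
   interpolation between extreme points chosen by Euclidean distance,
   with a 2 mm cutoff separating guide-wire gaps from bifurcations; the
   per-angle lumen border is the innermost Sobel edge of the bridged
   mask.
3. **Contour smoothing** — the closed radius signal r(θ) is smoothed
   with a Savitzky–Golay filter (window 35, order 2),

       (y_k)_s = Σ_{i=-n}^{n} A_i y_{k+i} / Σ_i A_i ,

   whose weights A_i realize a moving least-squares quadratic fit, then
   mapped back to Cartesian millimetres.
4. **Quantification** — lumen area (shoelace), mean/min/max diameter
   (centroid chords); between-method agreement via the mean difference,
   the relative difference RD = (1/N) Σ (I_i − O_i)/max(O_i, I_i) × 100%,
   its absolute counterpart ARD, ICC(2,1) with 95% CI, and Bland–Altman
   limits of agreement (mean ± 1.96 SD).

Because no clinical pullbacks are distributed, the package ships a
phantom generator that renders synthetic cross-sections (circle, ellipse
or Fourier-perturbed lumens; catheter ring, guide-wire spot + shadow,
bifurcation wedge, speckle) with exact analytic ground truth, so the
whole pipeline is testable end to end.  See `docs/methods.md` for the
modelling details.

## Worked example

```python
import numpy as np
from octlumen import PhantomSpec, PipelineConfig, CalibrationSpec
from octlumen.phantom import generate_phantom
from octlumen.pipeline import segment_frame

spec = PhantomSpec(lumen_shape="circle", radius_mm=1.5,
                   guide_wire=(120.0, 12.0), speckle_level=0.3, seed=1)
frame, truth = generate_phantom(spec)
result = segment_frame(frame, PipelineConfig(
    calibration=CalibrationSpec(catheter_diameter_mm=0.91)))
print(f"area {result.metrics.area_mm2:.3f} mm^2 "
      f"(truth {truth.metrics.area_mm2:.3f})")
print(f"diameters {result.metrics.min_diameter_mm:.2f}-"
      f"{result.metrics.max_diameter_mm:.2f} mm")
for b in result.contour.bridges:
    print(f"bridged gap of {b.gap_length_mm:.2f} mm "
          f"(bifurcation: {b.is_bifurcation})")
```

prints

```
area 7.081 mm^2 (truth 7.069)
diameters 3.00-3.02 mm
bridged gap of 0.33 mm (bifurcation: False)
bridged gap of 0.03 mm (bifurcation: False)
```

i.e. the 1.5 mm-radius lumen (area π·1.5² ≈ 7.07 mm², diameter 3 mm) is
recovered within about 1 %, and the 12° guide-wire shadow produced a
0.33 mm gap in the intima band that was bridged and correctly classified
as sub-bifurcation (< 2 mm).  The second, near-zero entry is the trivial
seam bridge where the angular axis wraps around.

The same pipeline runs from the shell:

```sh
octlumen segment pullback.dcm --out results/        # contours + metrics CSV
octlumen phantom --out phantom/                     # synthetic frame + truth
octlumen suite --seed 1 --out suite/                # phantom recovery table
octlumen compare metrics_a.csv metrics_b.csv --out cmp/
```

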