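"""Polar-domain preprocessing: catheter removal, despeckling, binarization.

The imaging catheter shows up as a bright band of known physical width at
the left edge of the polar image; its extent is computed from the
calibrated catheter diameter and blanked.  Speckle from residual blood is
suppressed with a 5x5 median filter followed by Gaussian smoothing, and
an automatic (Otsu) threshold yields the binary intima mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .frame_io import CalibrationSpec
from .polar_geometry import GeometryError, PolarImage

__all__ = ["PreprocessParams", "remove_catheter", "denoise", "binarize",
           "DegenerateHistogramError"]


class DegenerateHistogramError(ValueError):
    """Raised when an automatic threshold cannot be chosen (constant image)."""


@dataclass(frozen=True)
class PreprocessParams:
    """Despeckling and binarization settings.

    median_window : odd side of the square median window (default 5).
    gaussian_sigma_bins : Gaussian std-dev in polar bins (default 2; large
        enough to blur speckle remnants, small enough to keep the intima
        leading edge within about one bin).
    threshold_method : automatic threshold rule; only ``"otsu"`` is built in.
    catheter_margin_mm : blanked margin beyond the physical catheter radius,
        covering the sheath's bright reflection.
    """

    median_window: int = 5
    gaussian_sigma_bins: float = 2.0
    threshold_method: str = "otsu"
    catheter_margin_mm: float = 0.05

    def __post_init__(self) -> None:
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 3")
        if not self.gaussian_sigma_bins > 0:
            raise ValueError("gaussian_sigma_bins must be positive")
        if self.threshold_method != "otsu":
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")


def catheter_removal_width(
    calibration: CalibrationSpec, radial_spacing_mm: float, margin_mm: float = 0.05,
) -> int:
    """Number of innermost radius bins occupied by the catheter (+ margin)."""
    return math.ceil((calibration.catheter_diameter / 2.0 + margin_mm) / radial_spacing_mm)


def remove_catheter(
    polar: PolarImage, calibration: CalibrationSpec | None = None,
    margin_mm: float = 0.05,
) -> PolarImage:
    """Blank the catheter ring: zero the innermost radius bins in every A-line.

    Columns ``0 .. ceil((d/2 + margin)/spacing) - 1`` are set to 0; all
    other bins are untouched.
    """
    calibration = calibration or polar.calibration
    width = catheter_removal_width(calibration, polar.radial_spacing_mm, margin_mm)
    if width >= polar.n_radii:
        raise GeometryError(
            f"catheter region ({width} bins) covers the whole radial range "
            f"({polar.n_radii} bins)")
    values = polar.values.copy()
    values[:, :width] = 0.0
    return replace(polar, values=values)


def denoise(polar: PolarImage, params: PreprocessParams | None = None) -> PolarImage:
    """Median filter (square window, replicated edges) then Gaussian smoothing."""
    params = params or PreprocessParams()
    m = ndimage.median_filter(polar.values, size=params.median_window, mode="nearest")
    g = ndimage.gaussian_filter(m, sigma=params.gaussian_sigma_bins, mode="nearest")
    return replace(polar, values=g)


def binarize(polar: PolarImage, params: PreprocessParams | None = None) -> np.ndarray:
    """Threshold the polar image into a boolean tissue mask.

    The threshold maximizes Otsu's between-class variance over a 256-bin
    histogram; foreground is strictly above the threshold.
    """
    params = params or PreprocessParams()
    values = polar.values
    if np.ptp(values) == 0:
        raise DegenerateHistogramError("cannot threshold a constant image")
    thr = threshold_otsu(values, nbins=256)
    return values > thr
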