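"""Savitzky-Golay smoothing of the closed lumen contour.

The raw per-angle border is staircased by the binary segmentation; a
moving least-squares polynomial fit (Savitzky-Golay, window 35, order 2
by default) realized as a fixed symmetric convolution smooths the radius
signal.  The contour is closed, so the convolution wraps around the
angle axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import savgol_coeffs

from .polar_geometry import IncompleteContourError, PolarContour

__all__ = ["SavGolSpec", "savgol_coefficients", "smooth_contour"]


@dataclass(frozen=True)
class SavGolSpec:
    """Savitzky-Golay filter: window ``2n+1`` samples, polynomial order
    ``order``, and the derived convolution weights ``A_{-n}..A_n``
    (normalized to sum 1)."""

    window: int = 35
    order: int = 2
    coefficients: np.ndarray = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        if not 0 <= self.order < self.window:
            raise ValueError("order must satisfy 0 <= order < window")
        if self.coefficients is None:
            object.__setattr__(
                self, "coefficients", savgol_coeffs(self.window, self.order))

    @property
    def half_width(self) -> int:
        return self.window // 2


def savgol_coefficients(window: int, order: int) -> SavGolSpec:
    """Derive the least-squares polynomial-fit convolution weights.

    The weights are the classical Savitzky-Golay convolution integers
    (scaled so they sum to 1): convolving with them is exactly equivalent
    to fitting each window with a degree-``order`` polynomial and taking
    its central value.
    """
    return SavGolSpec(window=window, order=order)


def smooth_contour(contour: PolarContour, spec: SavGolSpec | None = None) -> PolarContour:
    """Cyclically convolve the per-angle radius signal with the filter weights.

    The angle axis is periodic (the vessel outline is closed), so the
    window wraps around instead of truncating at the sequence ends.
    """
    spec = spec or SavGolSpec()
    if not contour.all_valid:
        raise IncompleteContourError("contour must be fully valid before smoothing")
    if spec.window >= contour.n_angles:
        raise ValueError(
            f"window ({spec.window}) must be smaller than the number of "
            f"angles ({contour.n_angles})")
    smoothed = ndimage.convolve1d(
        contour.radius_per_angle, spec.coefficients, mode="wrap")
    return PolarContour(smoothed, contour.valid_mask.copy())
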