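"""Cartesian <-> polar resampling around the imaging catheter.

The catheter sits at the polar origin, so the circular vessel wall becomes
a straightened band: rows are angle bins (A-lines), columns are radius
bins with radius increasing left to right.  All segmentation happens in
this domain; the final contour is mapped back to Cartesian millimetres.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .frame_io import CalibrationSpec, OCTFrame

__all__ = ["PolarImage", "PolarContour", "to_polar", "contour_to_cartesian",
           "contours_to_dataframe", "write_contours_json"]


class GeometryError(ValueError):
    pass


class IncompleteContourError(ValueError):
    pass


@dataclass
class PolarImage:
    """A frame resampled over (angle, radius).

    ``values[a, r]`` samples the frame at angle ``2*pi*a/n_angles``
    (measured from +x, counterclockwise) and radius ``r`` pixels from the
    catheter center; ``radial_spacing_mm`` is mm per radius bin.
    """

    values: np.ndarray
    radial_spacing_mm: float
    calibration: CalibrationSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("polar values must be 2-D (angle x radius)")
        if self.n_angles < 8 or self.n_radii < 2:
            raise ValueError("polar grid too small (need >= 8 angles, >= 2 radii)")
        if not self.radial_spacing_mm > 0:
            raise ValueError("radial_spacing_mm must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("polar values must be finite")

    @property
    def n_angles(self) -> int:
        return self.values.shape[0]

    @property
    def n_radii(self) -> int:
        return self.values.shape[1]

    def angles_rad(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_angles) / self.n_angles


@dataclass
class PolarContour:
    """Per-angle lumen radius (in radius bins, fractional allowed)."""

    radius_per_angle: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.radius_per_angle = np.asarray(self.radius_per_angle, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.radius_per_angle.shape != self.valid_mask.shape:
            raise ValueError("radius and validity arrays must have equal shape")
        valid = self.radius_per_angle[self.valid_mask]
        if valid.size and valid.min() < 0:
            raise ValueError("valid radii must be non-negative")

    @property
    def n_angles(self) -> int:
        return self.radius_per_angle.size

    @property
    def all_valid(self) -> bool:
        return bool(self.valid_mask.all())


def max_inscribed_radius(frame: OCTFrame) -> float:
    """Distance (px) from the catheter center to the nearest image edge."""
    r, c = frame.center
    h, w = frame.intensity.shape
    return min(r, h - 1 - r, c, w - 1 - c)


def to_polar(frame: OCTFrame, n_angles: int = 360, n_radii: int | None = None) -> PolarImage:
    """Resample a Cartesian frame onto an (angle, radius) grid.

    Bilinear interpolation at ``center + r * (cos(theta), sin(theta))``
    with ``theta = 2*pi*a/n_angles``; angle 0 along +x (columns),
    counterclockwise through +y (rows).
    """
    if n_angles < 8:
        raise ValueError("n_angles must be >= 8")
    rmax = max_inscribed_radius(frame)
    if n_radii is None:
        n_radii = int(math.floor(rmax))
    if n_radii < 2:
        raise ValueError("n_radii must be >= 2")
    if n_radii - 1 > rmax:
        raise GeometryError(
            f"n_radii={n_radii} exceeds the in-image radius ({rmax:.1f} px)")
    theta = 2.0 * np.pi * np.arange(n_angles) / n_angles
    radii = np.arange(n_radii, dtype=float)
    cr, cc = frame.center
    rows = cr + radii[None, :] * np.sin(theta)[:, None]
    cols = cc + radii[None, :] * np.cos(theta)[:, None]
    values = ndimage.map_coordinates(
        frame.intensity, [rows, cols], order=1, mode="nearest")
    return PolarImage(values, radial_spacing_mm=frame.calibration.pixel_spacing_mm,
                      calibration=frame.calibration)


def contour_to_cartesian(contour: PolarContour, frame: OCTFrame) -> np.ndarray:
    """Map a fully valid polar contour to an ordered closed (x_mm, y_mm) list.

    Point ``a`` is ``center_mm + radius_a * spacing * (cos, sin)(theta_a)``;
    the list is ordered by angle and closed implicitly (last point is
    adjacent to the first).
    """
    if not contour.all_valid:
        bad = np.flatnonzero(~contour.valid_mask)
        raise IncompleteContourError(
            f"contour has {bad.size} invalid angles (first: {bad[:5].tolist()})")
    spacing = frame.calibration.pixel_spacing_mm
    theta = 2.0 * np.pi * np.arange(contour.n_angles) / contour.n_angles
    cr, cc = frame.center
    x = cc * spacing + contour.radius_per_angle * spacing * np.cos(theta)
    y = cr * spacing + contour.radius_per_angle * spacing * np.sin(theta)
    return np.column_stack([x, y])


def contours_to_dataframe(
    contours: dict[int, tuple[PolarContour, np.ndarray]],
    radial_spacing_mm: float,
) -> pd.DataFrame:
    """Tabulate per-frame contours as (frame_index, angle_deg, radius_mm, x_mm, y_mm)."""
    rows = []
    for frame_index in sorted(contours):
        contour, points = contours[frame_index]
        n = contour.n_angles
        rows.append(pd.DataFrame({
            "frame_index": frame_index,
            "angle_deg": 360.0 * np.arange(n) / n,
            "radius_mm": contour.radius_per_angle * radial_spacing_mm,
            "x_mm": points[:, 0],
            "y_mm": points[:, 1],
        }))
    return pd.concat(rows, ignore_index=True)


def write_contours_json(
    contours: dict[int, tuple[PolarContour, np.ndarray]],
    path: str | Path, radial_spacing_mm: float,
) -> None:
    doc = {
        "radial_spacing_mm": radial_spacing_mm,
        "frames": [
            {
                "frame_index": int(k),
                "radius_mm": (c.radius_per_angle * radial_spacing_mm).tolist(),
                "points_mm": pts.tolist(),
            }
            for k, (c, pts) in sorted(contours.items())
        ],
    }
    Path(path).write_text(json.dumps(doc))
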