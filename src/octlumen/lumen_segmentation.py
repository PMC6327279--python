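"""Binary-mask segmentation of the intima in the polar domain.

The thresholded polar image still carries residual-blood clutter and is
cut into disconnected pieces by guide-wire shadows and bifurcation
ostia.  This module cleans the mask with a disk open/close, traces each
8-connected intima component with its 8 boundary extreme points, bridges
consecutive components with straight interpolation segments chosen by
Euclidean distance between extrema (a 2 mm physical cutoff separates
guide-wire-scale gaps from true bifurcations), and finally reads off the
innermost tissue edge per A-line as the lumen border.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.filters import sobel
from skimage.measure import label
from skimage.morphology import disk

from .frame_io import CalibrationSpec
from .polar_geometry import PolarContour

__all__ = [
    "MorphologyParams", "ComponentExtrema", "GapBridge",
    "open_close", "trace_components", "bridge_gaps", "extract_border",
    "filter_small_components", "NoTissueError", "IncompleteSegmentationError",
]

#: Default bifurcation cutoff: gaps longer than this (chord length in mm)
#: are classified as bifurcations rather than guide-wire shadows.
BIFURCATION_CUTOFF_MM = 2.0

#: Extreme-point names in the conventional clockwise order.
EXTREMA_NAMES = (
    "top_left", "top_right", "right_top", "right_bottom",
    "bottom_right", "bottom_left", "left_bottom", "left_top",
)


class NoTissueError(ValueError):
    """The binary mask contains no foreground at all."""


class IncompleteSegmentationError(ValueError):
    """Some A-line has no tissue after bridging (bridging failed)."""


@dataclass(frozen=True)
class MorphologyParams:
    """Disk structuring-element radius for open/close (bins). The disk
    shape preserves the circular character of the lumen; radius 5 is the
    default working value."""

    disk_radius_bins: int = 5

    def __post_init__(self) -> None:
        if self.disk_radius_bins < 1:
            raise ValueError("disk_radius_bins must be >= 1")

    @property
    def footprint(self) -> np.ndarray:
        return disk(self.disk_radius_bins)


@dataclass
class ComponentExtrema:
    """One 8-connected foreground component with its boundary landmarks.

    ``extrema`` maps the eight conventional extreme-point names to
    (row, col) pixel coordinates; ``boundary`` is the closed, ordered,
    8-connected exterior boundary chain; ``pixels`` holds every (row, col)
    of the component (used for endpoint refinement).
    """

    component_id: int
    extrema: dict[str, tuple[int, int]]
    boundary: list[tuple[int, int]]
    pixels: np.ndarray = field(repr=False, default=None)

    @property
    def top_row(self) -> int:
        return self.extrema["top_left"][0]

    @property
    def bottom_row(self) -> int:
        return self.extrema["bottom_left"][0]


@dataclass(frozen=True)
class GapBridge:
    """One interpolated connection between consecutive intima components."""

    upper_point: tuple[int, int]
    lower_point: tuple[int, int]
    gap_length_mm: float
    is_bifurcation: bool


# --- morphology ------------------------------------------------------------

def _erode(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    # border_value=1: the image edge behaves as foreground, so structures
    # touching the edge are not eaten from outside (MATLAB convention).
    return ndimage.binary_erosion(mask, structure=footprint, border_value=1)


def _dilate(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return ndimage.binary_dilation(mask, structure=footprint, border_value=0)


def open_close(binary: np.ndarray, params: MorphologyParams | None = None) -> np.ndarray:
    """Morphological opening then closing with a flat disk of radius R.

    Opening removes foreground islands that cannot contain a translate of
    the disk; the subsequent closing fills background holes smaller than
    the disk, without changing the overall size of the retained regions.
    """
    params = params or MorphologyParams()
    fp = params.footprint
    mask = np.asarray(binary, dtype=bool)
    opened = _dilate(_erode(mask, fp), fp)
    closed = _erode(_dilate(opened, fp), fp)
    return closed


def filter_small_components(binary: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_area`` pixels.

    Residual blood clusters occasionally survive open/close at image
    edges; anything smaller than the structuring element's area cannot be
    intima.
    """
    lab, n = label(np.asarray(binary, bool), connectivity=2, return_num=True)
    if n == 0:
        return np.asarray(binary, bool).copy()
    counts = np.bincount(lab.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[lab]


# --- boundary tracing ------------------------------------------------------

# Clockwise 8-neighborhood offsets starting from "up" (in image coordinates).
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _moore_boundary(mask: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Ordered exterior boundary chain (Moore-neighbor tracing, Jacob's
    stopping criterion).  ``start`` must be the topmost-then-leftmost
    foreground pixel, whose left neighbor is guaranteed background."""
    h, w = mask.shape

    def fg(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    boundary = [start]
    cur = start
    backtrack = (start[0], start[1] - 1)
    first_move: tuple[tuple[int, int], tuple[int, int]] | None = None
    limit = 4 * int(mask.sum()) + 8
    for _ in range(limit):
        ring = [(cur[0] + dr, cur[1] + dc) for dr, dc in _MOORE]
        i0 = ring.index(backtrack)
        nxt = None
        for k in range(1, 9):
            cand = ring[(i0 + k) % 8]
            if fg(cand):
                nxt = cand
                new_backtrack = ring[(i0 + k - 1) % 8]
                break
        if nxt is None:  # isolated pixel
            break
        if (cur, nxt) == first_move:  # Jacob's criterion: initial move repeats
            break
        if first_move is None:
            first_move = (cur, nxt)
        boundary.append(nxt)
        cur, backtrack = nxt, new_backtrack
    if boundary[-1] == start and len(boundary) > 1:
        boundary.pop()
    return boundary


def _component_extrema(rows: np.ndarray, cols: np.ndarray) -> dict[str, tuple[int, int]]:
    """Eight extreme points with the conventional tie-breaks (e.g.
    ``top_left`` = leftmost among the topmost pixels)."""

    def pick(primary: np.ndarray, minimize_primary: bool,
             secondary: np.ndarray, minimize_secondary: bool) -> tuple[int, int]:
        pv = primary.min() if minimize_primary else primary.max()
        sel = primary == pv
        s = secondary[sel]
        sv = s.min() if minimize_secondary else s.max()
        idx = np.flatnonzero(sel & (secondary == sv))[0]
        return (int(rows[idx]), int(cols[idx]))

    return {
        "top_left": pick(rows, True, cols, True),
        "top_right": pick(rows, True, cols, False),
        "right_top": pick(cols, False, rows, True),
        "right_bottom": pick(cols, False, rows, False),
        "bottom_right": pick(rows, False, cols, False),
        "bottom_left": pick(rows, False, cols, True),
        "left_bottom": pick(cols, True, rows, False),
        "left_top": pick(cols, True, rows, True),
    }


def trace_components(binary: np.ndarray) -> list[ComponentExtrema]:
    """Label 8-connected foreground components, top to bottom.

    Each component carries its ordered exterior boundary chain and the
    eight boundary extreme points; components are ordered by their
    minimal angle row so gap bridging can walk the angular chain.
    """
    mask = np.asarray(binary, dtype=bool)
    lab, n = label(mask, connectivity=2, return_num=True)
    if n == 0:
        raise NoTissueError("binary mask has no foreground component")
    comps = []
    for cid in range(1, n + 1):
        rows, cols = np.nonzero(lab == cid)
        extrema = _component_extrema(rows, cols)
        comps.append(ComponentExtrema(
            component_id=cid,
            extrema=extrema,
            boundary=_moore_boundary(lab == cid, extrema["top_left"]),
            pixels=np.column_stack([rows, cols]),
        ))
    comps.sort(key=lambda c: c.top_row)
    return comps


# --- gap bridging ----------------------------------------------------------

def _point_mm(row: float, col: float, n_angles: int, spacing_mm: float) -> np.ndarray:
    theta = 2.0 * np.pi * (row % n_angles) / n_angles
    return col * spacing_mm * np.array([math.cos(theta), math.sin(theta)])


def _refine_endpoint(comp: ComponentExtrema, extreme: tuple[int, int],
                     depth: int, direction: int) -> tuple[int, int]:
    """Move ``depth`` rows into the component from an extreme point and
    anchor at the innermost (first white) pixel of that row; falls back
    toward the extreme's row when the component is too short."""
    rows = comp.pixels[:, 0]
    cols = comp.pixels[:, 1]
    for d in range(depth, -1, -1):
        target = extreme[0] + direction * d
        sel = rows == target
        if sel.any():
            return (int(target), int(cols[sel].min()))
    return extreme


def bridge_gaps(
    components: list[ComponentExtrema],
    polar: np.ndarray,
    calibration: CalibrationSpec,
    bifurcation_cutoff_mm: float = BIFURCATION_CUTOFF_MM,
    radial_spacing_mm: float | None = None,
    refine_depth_guidewire: int = 2,
    refine_depth_bifurcation: int = 5,
) -> tuple[np.ndarray, list[GapBridge]]:
    """Bridge angular gaps between consecutive intima components.

    For each consecutive pair (top to bottom, plus the angular wrap-around
    from the last component back to the first) the candidate endpoints are
    the upper component's ``bottom_left`` extreme and the lower
    component's ``top_left``/``top_right`` extremes; the closer lower
    endpoint (Euclidean distance in Cartesian mm) wins.  The distance is
    the physical gap length; gaps beyond the cutoff are flagged as
    bifurcations, which widens the endpoint-refinement search.  A straight
    pixel segment between the refined endpoints is set to foreground.
    Every gap kind (guide wire, bifurcation, artifact) is bridged.
    """
    if not components:
        raise NoTissueError("no components to bridge")
    mask = np.asarray(polar, dtype=bool).copy()
    n_angles = mask.shape[0]
    spacing = radial_spacing_mm if radial_spacing_mm is not None \
        else calibration.pixel_spacing_mm

    pairs: list[tuple[ComponentExtrema, ComponentExtrema, int]] = []
    for i in range(len(components) - 1):
        pairs.append((components[i], components[i + 1], 0))
    rows_covered = mask.any(axis=1)
    if len(components) > 1 or not rows_covered.all():
        # wrap-around: last component connects back to the first one
        pairs.append((components[-1], components[0], n_angles))

    bridges: list[GapBridge] = []
    for upper, lower, row_offset in pairs:
        up_pt = upper.extrema["bottom_left"]
        candidates = [lower.extrema["top_left"], lower.extrema["top_right"]]
        up_mm = _point_mm(*up_pt, n_angles, spacing)
        dists = [
            float(np.linalg.norm(
                _point_mm(c[0] + row_offset, c[1], n_angles, spacing) - up_mm))
            for c in candidates
        ]
        low_pt = candidates[int(np.argmin(dists))]
        gap_mm = min(dists)
        is_bif = gap_mm > bifurcation_cutoff_mm
        depth = refine_depth_bifurcation if is_bif else refine_depth_guidewire

        up_ref = _refine_endpoint(upper, up_pt, depth, direction=-1)
        low_ref = _refine_endpoint(lower, low_pt, depth, direction=+1)
        rr, cc = draw_line(up_ref[0], up_ref[1],
                           low_ref[0] + row_offset, low_ref[1])
        mask[rr % n_angles, cc] = True
        bridges.append(GapBridge(
            upper_point=up_pt, lower_point=low_pt,
            gap_length_mm=gap_mm, is_bifurcation=is_bif))
    return mask, bridges


# --- border extraction -----------------------------------------------------

def extract_border(binary: np.ndarray) -> PolarContour:
    """Per-A-line lumen border: the innermost tissue edge.

    A Sobel gradient-magnitude map localizes the edges of the bridged
    mask; within each angle row the innermost (smallest-radius) edge
    position on the tissue side is the lumen border.  A row without any
    foreground means bridging failed upstream.
    """
    mask = np.asarray(binary, dtype=bool)
    if not mask.any(axis=1).all():
        missing = np.flatnonzero(~mask.any(axis=1))
        raise IncompleteSegmentationError(
            f"{missing.size} A-lines have no tissue (first: {missing[:5].tolist()})")
    grad = sobel(mask.astype(float))
    radius = np.empty(mask.shape[0], dtype=float)
    for row in range(mask.shape[0]):
        on_edge = mask[row] & (grad[row] > 1e-9)
        cols = np.flatnonzero(on_edge)
        if cols.size == 0:  # row entirely foreground: border at the origin side
            cols = np.flatnonzero(mask[row])
        radius[row] = cols[0]
    return PolarContour(radius, np.ones(mask.shape[0], dtype=bool))
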