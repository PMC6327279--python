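"""Per-frame lumen metrics and between-method agreement statistics.

The clinical read-outs are lumen area and mean/min/max lumen diameter per
frame.  Two measurement series (e.g. automatic vs. manual ground truth)
are compared with the mean difference, the relative difference

    RD  = (1/N) * sum_i (I_i - O_i) / max(O_i, I_i) * 100%,

its absolute counterpart ARD (with |I_i - O_i| in the numerator), the
two-way random-effects absolute-agreement single-measure intraclass
correlation ICC(2,1) with its 95% CI, and Bland-Altman limits of
agreement (mean difference +/- 1.96 SD of the differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from shapely.geometry import LineString, Polygon

__all__ = [
    "LumenMetrics", "AgreementReport",
    "lumen_metrics", "relative_difference", "absolute_relative_difference",
    "icc", "bland_altman", "compare_series",
]


@dataclass(frozen=True)
class LumenMetrics:
    """Area and diameter summary of one lumen contour."""

    area_mm2: float
    mean_diameter_mm: float
    min_diameter_mm: float
    max_diameter_mm: float

    def __post_init__(self) -> None:
        if not self.area_mm2 > 0:
            raise ValueError("area must be positive")
        if not (self.min_diameter_mm <= self.mean_diameter_mm
                <= self.max_diameter_mm):
            raise ValueError("diameter summary must be ordered min <= mean <= max")

    def as_dict(self) -> dict[str, float]:
        return {
            "area_mm2": self.area_mm2,
            "mean_diameter_mm": self.mean_diameter_mm,
            "min_diameter_mm": self.min_diameter_mm,
            "max_diameter_mm": self.max_diameter_mm,
        }


PARAMETERS = ("area_mm2", "mean_diameter_mm", "min_diameter_mm", "max_diameter_mm")


@dataclass(frozen=True)
class AgreementReport:
    """Paired-series agreement between two measurement methods."""

    mean_difference: float
    rd_percent: float
    ard_percent: float
    icc: float
    icc_ci95: tuple[float, float]
    loa_low: float
    loa_high: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_difference": self.mean_difference,
            "rd_percent": self.rd_percent,
            "ard_percent": self.ard_percent,
            "icc": self.icc,
            "icc_ci95_low": self.icc_ci95[0],
            "icc_ci95_high": self.icc_ci95[1],
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
        }


def _ray_distance(polygon: Polygon, centroid: np.ndarray,
                  direction: np.ndarray, reach: float) -> float:
    ray = LineString([centroid, centroid + reach * direction])
    hit = polygon.exterior.intersection(ray)
    if hit.is_empty:
        return 0.0
    if hit.geom_type == "Point":
        pts = [hit]
    else:
        pts = [g for g in getattr(hit, "geoms", [hit]) if g.geom_type == "Point"]
        if not pts:  # ray grazes an edge: take the far end of the overlap
            pts = [hit.boundary.geoms[-1]] if hasattr(hit, "boundary") else []
    if not pts:
        return 0.0
    d = [float(np.hypot(p.x - centroid[0], p.y - centroid[1])) for p in pts]
    return min(d)


def lumen_metrics(contour: np.ndarray, n_rays: int = 180) -> LumenMetrics:
    """Area and centroid-chord diameters of a closed contour.

    Area is the shoelace polygon area (mm^2).  Diameters are chord
    lengths through the contour centroid at ``n_rays`` equally spaced
    directions: each chord is the sum of the border distances along a ray
    and its opposite; min/mean/max are taken over the directions.
    """
    points = np.asarray(contour, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 8:
        raise ValueError("contour must be an (N>=8, 2) point list")
    if n_rays < 1:
        raise ValueError("n_rays must be positive")
    polygon = Polygon(points)
    if not polygon.is_valid or polygon.area <= 0:
        raise ValueError("contour is self-intersecting or degenerate")
    centroid = np.array([polygon.centroid.x, polygon.centroid.y])
    span = points - centroid
    reach = 2.0 * float(np.hypot(span[:, 0], span[:, 1]).max()) + 1.0
    theta = np.pi * np.arange(n_rays) / n_rays
    chords = np.empty(n_rays)
    for i, t in enumerate(theta):
        direction = np.array([np.cos(t), np.sin(t)])
        chords[i] = (_ray_distance(polygon, centroid, direction, reach)
                     + _ray_distance(polygon, centroid, -direction, reach))
    return LumenMetrics(
        area_mm2=float(polygon.area),
        mean_diameter_mm=float(chords.mean()),
        min_diameter_mm=float(chords.min()),
        max_diameter_mm=float(chords.max()),
    )


def _paired(first, second) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(first, dtype=float)
    i = np.asarray(second, dtype=float)
    if o.shape != i.shape or o.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    return o, i


def relative_difference(first, second) -> float:
    """Signed relative difference in percent (second relative to first).

    ``RD = (1/N) sum (I_i - O_i)/max(O_i, I_i) * 100`` with ``O`` the
    first and ``I`` the second series; all values must be positive.
    """
    o, i = _paired(first, second)
    if (o <= 0).any() or (i <= 0).any():
        raise ValueError("relative differences require strictly positive values")
    return float(np.mean((i - o) / np.maximum(o, i)) * 100.0)


def absolute_relative_difference(first, second) -> float:
    """Unsigned counterpart of :func:`relative_difference` (percent)."""
    o, i = _paired(first, second)
    if (o <= 0).any() or (i <= 0).any():
        raise ValueError("relative differences require strictly positive values")
    return float(np.mean(np.abs(i - o) / np.maximum(o, i)) * 100.0)


def icc(first, second) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Returns the coefficient and its 95% confidence interval (F-based).
    """
    o, i = _paired(first, second)
    if o.size < 3:
        raise ValueError("ICC needs at least 3 paired frames")
    if np.ptp(o) == 0 or np.ptp(i) == 0:
        raise ValueError("ICC is undefined for constant series")
    n = o.size
    data = pd.DataFrame({
        "frame": np.tile(np.arange(n), 2),
        "method": np.repeat(["first", "second"], n),
        "value": np.concatenate([o, i]),
    })
    import warnings

    with warnings.catch_warnings():
        # zero residual variance (perfect agreement) trips benign
        # divide-by-zero warnings inside the ANOVA
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=data, targets="frame", raters="method", ratings="value")
    # two-way random, absolute agreement, single measure: ICC(2,1) in the
    # Shrout-Fleiss nomenclature, ICC(A,1) in McGraw-Wong (label varies
    # across pingouin versions)
    sel = table["Type"].isin(["ICC2", "ICC(A,1)"])
    row = table[sel].iloc[0]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    value = float(row["ICC"])
    lo, hi = (float(v) for v in row[ci_col])
    if not (np.isfinite(lo) and np.isfinite(hi)):  # degenerate: zero error variance
        lo = hi = value
    return value, (lo, hi)


def bland_altman(first, second):
    """Bland-Altman agreement: mean difference and 1.96-SD limits.

    Returns ``(mean_difference, loa_low, loa_high, pair_means,
    pair_differences)`` with differences ``first - second`` and the
    sample (N-1) standard deviation.
    """
    o, i = _paired(first, second)
    if o.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = o - i
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    return (mean_d, mean_d - 1.96 * sd, mean_d + 1.96 * sd, (o + i) / 2.0, d)


def compare_series(first, second) -> AgreementReport:
    """Full agreement summary between two aligned measurement series."""
    mean_d, lo, hi, _, _ = bland_altman(first, second)
    icc_val, ci = icc(first, second)
    return AgreementReport(
        mean_difference=mean_d,
        rd_percent=relative_difference(first, second),
        ard_percent=absolute_relative_difference(first, second),
        icc=icc_val,
        icc_ci95=ci,
        loa_low=lo,
        loa_high=hi,
    )
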