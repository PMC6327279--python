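"""Published clinical validation summary shipped for agreement arithmetic.

Per-frame measurements of the 667-frame clinical validation study are
not publicly deposited; what is published are the per-method means of
the four lumen parameters (automatic method, two commercial systems and
the manual ground truth) and the pairwise mean differences.  They are
included here so the agreement arithmetic (mean difference = first
method minus second method) can be checked against the printed summary
without the raw data.
"""

from __future__ import annotations

__all__ = ["METHOD_MEANS", "REPORTED_MEAN_DIFFERENCES", "mean_difference"]

#: Published per-method means: mm^2 for lumen area, mm for diameters.
METHOD_MEANS: dict[str, dict[str, float]] = {
    "our_method": {
        "area_mm2": 5.99,
        "mean_diameter_mm": 2.72,
        "min_diameter_mm": 2.52,
        "max_diameter_mm": 2.91,
    },
    "system_1": {
        "area_mm2": 6.04,
        "mean_diameter_mm": 2.72,
        "min_diameter_mm": 2.52,
        "max_diameter_mm": 2.93,
    },
    "system_2": {
        "area_mm2": 5.76,
        "mean_diameter_mm": 2.66,
        "min_diameter_mm": 2.42,
        "max_diameter_mm": 2.87,
    },
    "ground_truth": {
        "area_mm2": 5.89,
        "mean_diameter_mm": 2.68,
        "min_diameter_mm": 2.49,
        "max_diameter_mm": 2.88,
    },
}

#: Published pairwise mean differences (first minus second) for the
#: method-vs-ground-truth and method-vs-system-1 comparisons.
REPORTED_MEAN_DIFFERENCES: dict[tuple[str, str, str], float] = {
    ("our_method", "ground_truth", "area_mm2"): 0.10,
    ("our_method", "ground_truth", "min_diameter_mm"): 0.03,
    ("our_method", "system_1", "min_diameter_mm"): 0.00,
}


def mean_difference(first: str, second: str, parameter: str) -> float:
    """Mean difference (first-listed method minus second) from the
    published per-method means, rounded to the printed precision."""
    return round(METHOD_MEANS[first][parameter] - METHOD_MEANS[second][parameter], 2)
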