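"""End-to-end orchestration: frames in, contours and metrics out.

The stage order mirrors the method: read -> overlay removal -> grayscale
-> polar transform -> catheter removal -> despeckle -> binarize ->
open/close -> component tracing -> gap bridging -> border extraction ->
Savitzky-Golay smoothing -> Cartesian back-transform -> metrics.  Frames
that fail at any stage are logged and reported as missing rows; a
pullback is never aborted because of a single bad frame.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import lumen_segmentation as seg
from . import preprocess as pre
from .contour_postprocess import SavGolSpec, smooth_contour
from .frame_io import CalibrationSpec, OCTFrame, read_pullback
from .lumen_segmentation import BIFURCATION_CUTOFF_MM, GapBridge, MorphologyParams
from .polar_geometry import (PolarContour, contour_to_cartesian,
                             contours_to_dataframe, to_polar)
from .preprocess import PreprocessParams
from .quantification import PARAMETERS, LumenMetrics, compare_series, lumen_metrics

__all__ = ["PipelineConfig", "LumenContour", "FrameResult",
           "segment_frame", "segment_pullback", "compare_methods"]

METRIC_COLUMNS = ["frame_index", *PARAMETERS]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline; the defaults are the method's
    working constants (5x5 median, R=5 disk, Savitzky-Golay window 35 /
    order 2, 2 mm bifurcation cutoff)."""

    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    savgol: SavGolSpec = field(default_factory=SavGolSpec)
    n_angles: int = 360
    n_radii: int | None = None
    bifurcation_cutoff_mm: float = BIFURCATION_CUTOFF_MM
    n_rays: int = 180

    def to_dict(self) -> dict:
        d = asdict(self)
        d["savgol"] = {"window": self.savgol.window, "order": self.savgol.order}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "calibration" in d:
            d["calibration"] = CalibrationSpec(**d["calibration"])
        if "preprocess" in d:
            d["preprocess"] = PreprocessParams(**d["preprocess"])
        if "morphology" in d:
            d["morphology"] = MorphologyParams(**d["morphology"])
        if "savgol" in d:
            d["savgol"] = SavGolSpec(**d["savgol"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class LumenContour:
    """Final per-frame output: smoothed polar radii plus the ordered
    closed Cartesian point list in mm."""

    polar: PolarContour
    points_mm: np.ndarray
    bridges: list[GapBridge]


@dataclass
class FrameResult:
    frame_index: int
    contour: LumenContour
    metrics: LumenMetrics
    stage_log: list[dict]


def segment_frame(frame: OCTFrame, config: PipelineConfig | None = None) -> FrameResult:
    """Run the whole segmentation chain on one calibrated frame."""
    config = config or PipelineConfig()
    calibration = frame.calibration
    log: list[dict] = []

    def logged(stage: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        out = fn(*args, **kwargs)
        log.append({"stage": stage, "seconds": time.perf_counter() - t0})
        return out

    polar = logged("to_polar", to_polar, frame, config.n_angles, config.n_radii)
    polar = logged("remove_catheter", pre.remove_catheter, polar, calibration,
                   config.preprocess.catheter_margin_mm)
    polar = logged("denoise", pre.denoise, polar, config.preprocess)
    binary = logged("binarize", pre.binarize, polar, config.preprocess)
    binary = logged("open_close", seg.open_close, binary, config.morphology)
    binary = logged("filter_small", seg.filter_small_components, binary,
                    int(config.morphology.footprint.sum()))
    components = logged("trace_components", seg.trace_components, binary)
    bridged, bridges = logged(
        "bridge_gaps", seg.bridge_gaps, components, binary, calibration,
        config.bifurcation_cutoff_mm, polar.radial_spacing_mm)
    border = logged("extract_border", seg.extract_border, bridged)
    smoothed = logged("smooth", smooth_contour, border, config.savgol)
    points = logged("to_cartesian", contour_to_cartesian, smoothed, frame)
    metrics = logged("metrics", lumen_metrics, points, config.n_rays)
    contour = LumenContour(polar=smoothed, points_mm=points, bridges=bridges)
    return FrameResult(frame.frame_index, contour, metrics, log)


def segment_pullback(
    input_path: str | Path | list[OCTFrame],
    config: PipelineConfig | None = None,
    output_dir: str | Path | None = None,
) -> tuple[list[FrameResult], list[dict]]:
    """Segment every frame of a pullback; failures are logged, not raised.

    Returns the successful per-frame results and a failure log (one entry
    per failed frame with the stage and reason).  When ``output_dir`` is
    given, writes ``contours.csv``, ``contours.json``, ``metrics.csv``
    and ``run_log.json``.
    """
    config = config or PipelineConfig()
    if isinstance(input_path, (str, Path)):
        frames = read_pullback(input_path, config.calibration)
    else:
        frames = list(input_path)
    results: list[FrameResult] = []
    failures: list[dict] = []
    for frame in frames:
        try:
            results.append(segment_frame(frame, config))
        except Exception as exc:  # noqa: BLE001 - per-frame isolation
            failures.append({
                "frame_index": frame.frame_index,
                "stage": type(exc).__name__,
                "reason": str(exc),
            })
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics_df = pd.DataFrame(
            [{"frame_index": r.frame_index, **r.metrics.as_dict()} for r in results],
            columns=METRIC_COLUMNS)
        metrics_df.to_csv(out / "metrics.csv", index=False)
        contour_map = {r.frame_index: (r.contour.polar, r.contour.points_mm)
                       for r in results}
        if contour_map:
            spacing = config.calibration.pixel_spacing_mm
            contours_to_dataframe(contour_map, spacing).to_csv(
                out / "contours.csv", index=False)
            from .polar_geometry import write_contours_json
            write_contours_json(contour_map, out / "contours.json", spacing)
        run_log = {
            "config": config.to_dict(),
            "n_frames": len(frames),
            "n_segmented": len(results),
            "failures": failures,
            "stages": [
                {"frame_index": r.frame_index, "log": r.stage_log}
                for r in results
            ],
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return results, failures


class FrameAlignmentError(ValueError):
    pass


def compare_methods(
    metrics_a: str | Path | pd.DataFrame,
    metrics_b: str | Path | pd.DataFrame,
    output_dir: str | Path | None = None,
) -> dict[str, dict]:
    """Agreement report per lumen parameter between two metric tables.

    Inputs are metric CSVs (or DataFrames) with columns ``frame_index,
    area_mm2, mean_diameter_mm, min_diameter_mm, max_diameter_mm`` aligned
    on ``frame_index``.  Emits difference, RD, ARD, ICC with CI and
    Bland-Altman limits plus the per-pair plot data for each parameter.
    """
    a = pd.read_csv(metrics_a) if isinstance(metrics_a, (str, Path)) else metrics_a
    b = pd.read_csv(metrics_b) if isinstance(metrics_b, (str, Path)) else metrics_b
    ia, ib = set(a["frame_index"]), set(b["frame_index"])
    if ia != ib:
        raise FrameAlignmentError(
            f"frame indices differ: only-first={sorted(ia - ib)}, "
            f"only-second={sorted(ib - ia)}")
    a = a.sort_values("frame_index").reset_index(drop=True)
    b = b.sort_values("frame_index").reset_index(drop=True)
    report: dict[str, dict] = {}
    for param in PARAMETERS:
        rep = compare_series(a[param].to_numpy(), b[param].to_numpy())
        entry = rep.as_dict()
        entry["bland_altman_mean"] = ((a[param] + b[param]) / 2).tolist()
        entry["bland_altman_diff"] = (a[param] - b[param]).tolist()
        report[param] = entry
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "agreement.json").write_text(json.dumps(report, indent=2))
        pd.DataFrame({
            p: {k: v for k, v in report[p].items() if not isinstance(v, list)}
            for p in PARAMETERS
        }).T.to_csv(out / "agreement.csv")
    return report
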