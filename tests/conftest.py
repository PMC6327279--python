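import numpy as np
import pytest

from octlumen.frame_io import CalibrationSpec, OCTFrame
from octlumen.phantom import PhantomSpec, default_suite, generate_phantom
from octlumen.pipeline import PipelineConfig, segment_frame


@pytest.fixture(scope="session")
def calibration():
    return CalibrationSpec(pixel_spacing_mm=0.01, catheter_gauge_french=2.7,
                           catheter_diameter_mm=0.91)


@pytest.fixture(scope="session")
def clean_circle_phantom():
    """Artifact-free circular lumen of radius 1.5 mm."""
    return generate_phantom(PhantomSpec(lumen_shape="circle", radius_mm=1.5))


def circle_frame(radius_px: float, size: int = 129, value: float = 1.0) -> OCTFrame:
    """A frame that is a single bright disk centered on the grid."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.where(np.hypot(yy - c, xx - c) <= radius_px, value, 0.0)
    return OCTFrame(img, 0, CalibrationSpec())


@pytest.fixture(scope="session")
def suite_runs():
    """Full pipeline on the standard 24-phantom recovery suite.

    One record per phantom: spec, ground truth and either the frame
    result or the caught exception.  Session-scoped because the suite
    backs several end-to-end checks.
    """
    config = PipelineConfig(calibration=CalibrationSpec(catheter_diameter_mm=0.91))
    records = []
    for spec in default_suite(seed=7, n_phantoms=24):
        frame, truth = generate_phantom(spec)
        try:
            result = segment_frame(frame, config)
            error = None
        except Exception as exc:  # noqa: BLE001
            result, error = None, exc
        records.append({"spec": spec, "truth": truth,
                        "result": result, "error": error})
    return records
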