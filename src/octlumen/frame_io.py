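"""Reading intracoronary OCT pullbacks and single frames.

Clinical OCT consoles export pullback runs as multiframe DICOM files in
which every frame is an RGB Cartesian cross-section with burnt-in colored
overlays (scale bars, calibration markers, text).  This module strips the
overlays, converts to NTSC grayscale and attaches physical calibration
(pixel spacing, catheter gauge) so that downstream stages can work in
millimetres.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

__all__ = [
    "CalibrationSpec",
    "OCTFrame",
    "read_pullback",
    "remove_color_overlays",
    "rgb_to_gray_ntsc",
    "write_frame_png",
    "write_pullback_dicom",
    "load_config",
]

#: NTSC 1953 luma weights for R, G, B.
NTSC_WEIGHTS = (0.299, 0.587, 0.114)

#: French catheter gauge: 1 Fr = 1/3 mm outer diameter.
MM_PER_FRENCH = 1.0 / 3.0

#: Default isotropic pixel spacing (mm/px), consistent with the 10-20 um
#: axial resolution of frequency-domain OCT.
DEFAULT_PIXEL_SPACING_MM = 0.01

RASTER_SUFFIXES = {".png", ".tif", ".tiff"}


class InputFormatError(ValueError):
    """Raised when a pullback file cannot be interpreted."""


@dataclass(frozen=True)
class CalibrationSpec:
    """Physical calibration of a pullback.

    Parameters
    ----------
    pixel_spacing_mm:
        Isotropic length of one pixel in mm.
    catheter_gauge_french:
        Imaging-catheter outer diameter in French units (1 Fr = 1/3 mm).
    catheter_diameter_mm:
        Explicit catheter diameter override in mm.  Vendors round the
        French conversion (a 2.7 Fr Dragonfly catheter is quoted as
        0.91 mm, not 0.90 mm), so the printed value can be set verbatim;
        when ``None`` the diameter is derived from the gauge.
    """

    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    catheter_gauge_french: float = 2.7
    catheter_diameter_mm: float | None = None

    def __post_init__(self) -> None:
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.catheter_gauge_french is not None and not self.catheter_gauge_french > 0:
            raise ValueError("catheter_gauge_french must be positive")
        if self.catheter_diameter_mm is not None and self.catheter_diameter_mm < 0:
            raise ValueError("catheter_diameter_mm must be non-negative "
                             "(0 means no catheter to remove)")

    @property
    def catheter_diameter(self) -> float:
        """Catheter outer diameter in mm (explicit override wins)."""
        if self.catheter_diameter_mm is not None:
            return self.catheter_diameter_mm
        return self.catheter_gauge_french * MM_PER_FRENCH


@dataclass
class OCTFrame:
    """One calibrated grayscale OCT cross-section on a square pixel grid."""

    intensity: np.ndarray
    frame_index: int
    calibration: CalibrationSpec
    center: tuple[float, float] | None = None  # (row, col); None = image center

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2 or self.intensity.shape[0] != self.intensity.shape[1]:
            raise ValueError("frame intensity grid must be 2-D and square")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("frame intensities must be finite")
        if self.intensity.min() < 0 or self.intensity.max() > 1:
            raise ValueError("frame intensities must lie in [0, 1]")
        if self.center is None:
            n = self.intensity.shape[0]
            self.center = ((n - 1) / 2.0, (n - 1) / 2.0)
        r, c = self.center
        h, w = self.intensity.shape
        if not (0 < r < h - 1 and 0 < c < w - 1):
            raise ValueError("catheter center must lie strictly inside the grid")

    @property
    def size_px(self) -> int:
        return self.intensity.shape[0]


def rgb_to_gray_ntsc(rgb: np.ndarray) -> np.ndarray:
    """Convert an RGB image to grayscale with the NTSC 1953 luma weights.

    ``gray = 0.299 R + 0.587 G + 0.114 B``; channels must lie in [0, 1].
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    w = np.asarray(NTSC_WEIGHTS)
    return rgb @ w


def remove_color_overlays(rgb: np.ndarray, saturation_tol: float = 0.1) -> np.ndarray:
    """Blank out colored (non-achromatic) pixels.

    Burnt-in overlays (scale bars, markers, text) are colored while OCT
    signal is gray.  Any pixel whose channel spread ``max(R,G,B) -
    min(R,G,B)`` exceeds ``saturation_tol`` (as a fraction of full scale)
    is replaced by background (0).
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    scale = max(rgb.max(), 1.0)
    spread = (rgb.max(axis=-1) - rgb.min(axis=-1)) / scale
    out = rgb.copy()
    out[spread > saturation_tol] = 0.0
    return out


def _normalize_gray(img: np.ndarray) -> np.ndarray:
    """Rescale an integer/float grayscale image into [0, 1]."""
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(float) / np.iinfo(img.dtype).max
    img = img.astype(float)
    if img.size and img.max() > 1.0:
        img = img / img.max()
    return np.clip(img, 0.0, 1.0)


def _frame_from_array(
    arr: np.ndarray, index: int, calibration: CalibrationSpec,
    center: tuple[float, float] | None,
) -> OCTFrame:
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.ndim == 3 and arr.shape[-1] == 3:
        rgb = arr.astype(float)
        if np.issubdtype(arr.dtype, np.integer):
            rgb = rgb / np.iinfo(arr.dtype).max
        rgb = remove_color_overlays(rgb)
        gray = rgb_to_gray_ntsc(rgb)
        gray = np.clip(gray, 0.0, 1.0)
    elif arr.ndim == 2:
        gray = _normalize_gray(arr)
    else:
        raise InputFormatError(f"unsupported frame shape {arr.shape}")
    return OCTFrame(gray, frame_index=index, calibration=calibration, center=center)


def _read_dicom(path: Path, calibration: CalibrationSpec,
                center: tuple[float, float] | None) -> list[OCTFrame]:
    try:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
    except Exception as exc:  # noqa: BLE001 - normalize to input error
        raise InputFormatError(f"cannot read DICOM {path}: {exc}") from exc
    if "PixelSpacing" in ds:
        spacing = float(ds.PixelSpacing[0])
        calibration = replace(calibration, pixel_spacing_mm=spacing)
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if n_frames > 1 or arr.ndim == 4 or (arr.ndim == 3 and arr.shape[-1] != 3):
        frames = [arr[i] for i in range(arr.shape[0])]
    else:
        frames = [arr]
    return [_frame_from_array(f, i, calibration, center) for i, f in enumerate(frames)]


def read_pullback(
    path: str | Path,
    calibration: CalibrationSpec | None = None,
    center: tuple[float, float] | None = None,
) -> list[OCTFrame]:
    """Read a pullback (multiframe DICOM or directory of rasters) or a
    single raster frame.

    Returns one :class:`OCTFrame` per stored frame, in storage order, with
    0-based contiguous ``frame_index``.  RGB sources pass through
    :func:`remove_color_overlays` and :func:`rgb_to_gray_ntsc`.
    """
    path = Path(path)
    calibration = calibration or CalibrationSpec()
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in RASTER_SUFFIXES)
        if not files:
            raise InputFormatError(f"no raster frames found in directory {path}")
        return [
            _frame_from_array(iio.imread(p), i, calibration, center)
            for i, p in enumerate(files)
        ]
    if path.suffix.lower() in RASTER_SUFFIXES:
        return [_frame_from_array(iio.imread(path), 0, calibration, center)]
    frames = _read_dicom(path, calibration, center)
    if not frames:
        raise InputFormatError(f"{path} contains zero frames")
    return frames


def write_frame_png(frame: OCTFrame, path: str | Path) -> None:
    """Export a frame as a lossless 16-bit grayscale PNG."""
    arr = np.round(frame.intensity * 65535).astype(np.uint16)
    iio.imwrite(Path(path), arr)


def write_pullback_dicom(
    frames: Sequence[np.ndarray], path: str | Path,
    pixel_spacing_mm: float | None = None, rgb: bool = False,
) -> None:
    """Write float [0,1] frames as an 8-bit secondary-capture multiframe DICOM.

    Used to build synthetic pullback files; mirrors the layout the reader
    expects (frames stored first-axis-major, optional ``PixelSpacing``).
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if not frames:
        raise ValueError("need at least one frame")
    h, w = frames[0].shape[:2]
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OCT"
    ds.Rows, ds.Columns = h, w
    ds.NumberOfFrames = len(frames)
    ds.BitsAllocated = ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    if rgb:
        ds.SamplesPerPixel = 3
        ds.PhotometricInterpretation = "RGB"
        ds.PlanarConfiguration = 0
    else:
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
    if pixel_spacing_mm is not None:
        ds.PixelSpacing = [pixel_spacing_mm, pixel_spacing_mm]
    stack = np.stack([np.round(f * 255).astype(np.uint8) for f in frames])
    ds.PixelData = stack.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def load_config(path: str | Path) -> dict:
    """Parse a ``key=value`` calibration/config file.

    Recognized keys: ``pixel_spacing_mm``, ``catheter_gauge_french``,
    ``catheter_diameter_mm``, ``center_row``, ``center_col``.  Lines
    starting with ``#`` are comments.  Values are parsed as floats.
    """
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = re.match(r"^([A-Za-z_][A-Za-z0-9_]*)\s*=\s*(.+)$", line)
        if not m:
            raise ValueError(f"cannot parse config line: {line!r}")
        out[m.group(1)] = float(m.group(2))
    return out


def calibration_from_config(cfg: dict) -> CalibrationSpec:
    kwargs = {}
    for key in ("pixel_spacing_mm", "catheter_gauge_french", "catheter_diameter_mm"):
        if key in cfg:
            kwargs[key] = cfg[key]
    return CalibrationSpec(**kwargs)
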