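"""The bench's two measurements.

*Transmission* is the photocell signal through the illumination fibres,
scaled so that the calibration signal (source directly on the cell) reads
100 units.

*Contrast* is a histogram-quantile statistic on the captured image inside a
circular region of interest: the grey-level distance between the points
where the ascending cumulative pixel count reaches 25% and 75% of the ROI
pixel count. Quantiles use the smallest grey level whose cumulative count
reaches ``ceil(q * N)`` — no interpolation, so the statistic is exactly the
difference of two order statistics of the ROI pixels. Per-frequency
contrasts are averaged over the seven line patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime

import numpy as np
from scipy import ndimage

from .errors import CalibrationError, InvalidArgumentError, RoiNotFoundError
from .patterns import N_LINE_FREQUENCIES
from .registry import Context, MeasurementRecord

__all__ = [
    "ROISpec",
    "ContrastResult",
    "TransmissionResult",
    "locate_roi",
    "compute_contrast",
    "average_contrast",
    "compute_transmission",
    "measure_endoscope",
]

#: minimum fraction of the frame the bright ROI component must cover
MIN_ROI_AREA_FRACTION = 0.005


@dataclass(frozen=True)
class ROISpec:
    """Circular region of interest: centre (row, col) and radius, in pixels."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidArgumentError(f"ROI radius must be > 0, got {self.radius}")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        cy, cx = self.center
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= self.radius**2


@dataclass(frozen=True)
class ContrastResult:
    per_frequency: tuple[float, ...]
    average: float


@dataclass(frozen=True)
class TransmissionResult:
    units: float
    calibration_signal: float
    endoscope_signal: float


def locate_roi(roi_image: np.ndarray) -> ROISpec:
    """Recover the ROI disc from a captured ROI-circle image.

    Thresholds at the midpoint of the 10th and 90th grey percentiles, keeps
    the largest bright connected component, and returns its centroid and
    equivalent-area radius.
    """
    img = np.asarray(roi_image, dtype=float)
    if img.ndim != 2:
        raise InvalidArgumentError("roi_image must be 2-D")
    p10, p90 = np.percentile(img, [10, 90])
    threshold = (p10 + p90) / 2.0
    bright = img > threshold
    labels, n_components = ndimage.label(bright)
    if n_components == 0:
        raise RoiNotFoundError("no bright pixels above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_components + 1))
    best = int(np.argmax(sizes)) + 1
    area = float(sizes[best - 1])
    if area < MIN_ROI_AREA_FRACTION * img.size:
        raise RoiNotFoundError(
            f"largest bright component covers {area / img.size:.2%} of the frame, "
            f"below the {MIN_ROI_AREA_FRACTION:.2%} minimum"
        )
    cy, cx = ndimage.center_of_mass(labels == best)
    radius = math.sqrt(area / math.pi)
    return ROISpec(center=(float(cy), float(cx)), radius=radius)


def _quantile_grey(counts: np.ndarray, rank: int) -> int:
    """Smallest grey level whose ascending cumulative count reaches ``rank``."""
    cum = np.cumsum(counts)
    return int(np.searchsorted(cum, rank, side="left"))


def compute_contrast(image: np.ndarray, roi: ROISpec) -> float:
    """Grey-level distance between the 25% and 75% cumulative-count points."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise InvalidArgumentError("image must be 2-D")
    mask = roi.mask(img.shape)
    pixels = img[mask]
    n = pixels.size
    if n == 0:
        raise InvalidArgumentError("ROI contains no pixels")
    counts = np.bincount(pixels.astype(np.int64).ravel(), minlength=256)
    g25 = _quantile_grey(counts, math.ceil(0.25 * n))
    g75 = _quantile_grey(counts, math.ceil(0.75 * n))
    return float(g75 - g25)


def average_contrast(per_frequency: list[float]) -> ContrastResult:
    """Arithmetic mean over the seven line-frequency contrasts."""
    if len(per_frequency) != N_LINE_FREQUENCIES:
        raise InvalidArgumentError(
            f"expected {N_LINE_FREQUENCIES} per-frequency contrasts, "
            f"got {len(per_frequency)}"
        )
    values = tuple(float(v) for v in per_frequency)
    if any(not 0 <= v <= 255 for v in values):
        raise InvalidArgumentError("contrast values must be in [0, 255]")
    return ContrastResult(per_frequency=values, average=float(np.mean(values)))


def compute_transmission(reading) -> TransmissionResult:
    """Transmission units: 100 x endoscope signal / calibration signal."""
    cal = float(reading.calibration_signal)
    sig = float(reading.endoscope_signal)
    if cal <= 0:
        raise CalibrationError(f"calibration signal must be > 0, got {cal}")
    if sig < 0:
        raise InvalidArgumentError(f"endoscope signal must be >= 0, got {sig}")
    return TransmissionResult(
        units=100.0 * sig / cal,
        calibration_signal=cal,
        endoscope_signal=sig,
    )


def measure_endoscope(
    line_captures: list[np.ndarray],
    roi_capture: np.ndarray,
    reading,
    moisture_observed: bool,
    *,
    serial: str,
    type_id: str,
    timestamp: datetime,
    context: Context = Context.CLINICAL,
) -> MeasurementRecord:
    """Full measurement session: ROI location, per-frequency contrast,
    contrast average, and transmission, assembled into an unstored record.
    """
    if len(line_captures) != N_LINE_FREQUENCIES:
        raise InvalidArgumentError(
            f"expected {N_LINE_FREQUENCIES} line captures, got {len(line_captures)}"
        )
    shapes = {np.asarray(c).shape for c in line_captures}
    shapes.add(np.asarray(roi_capture).shape)
    if len(shapes) != 1:
        raise InvalidArgumentError(f"captures differ in size: {sorted(shapes)}")
    roi = locate_roi(roi_capture)
    contrast = average_contrast([compute_contrast(c, roi) for c in line_captures])
    transmission = compute_transmission(reading)
    return MeasurementRecord(
        serial=serial,
        type_id=type_id,
        timestamp=timestamp,
        transmission=transmission.units,
        contrast=contrast.average,
        moisture=bool(moisture_observed),
        context=context,
    )
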