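"""On-screen test patterns for the virtual bench.

Seven binary line patterns of increasing spatial frequency probe the viewing
pathway; a single centred disc pattern defines the circular region of
interest in which contrast is evaluated.

Line periods follow a geometric series, ``period(i) ~ size / (4 * 2**(i/2))``
rounded to the nearest even integer so the 50% duty cycle stays exact.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InvalidArgumentError

__all__ = [
    "PatternKind",
    "Orientation",
    "TestPattern",
    "line_period",
    "generate_line_pattern",
    "generate_roi_pattern",
    "default_pattern_suite",
    "load_pattern",
]

N_LINE_FREQUENCIES = 7
DEFAULT_RADIUS_FRACTION = 0.4

BLACK = 0
WHITE = 255


class PatternKind(str, enum.Enum):
    LINES = "LINES"
    ROI_CIRCLE = "ROI_CIRCLE"
    UNIFORM = "UNIFORM"


class Orientation(str, enum.Enum):
    #: grey level varies along the x (column) axis -> vertical stripes
    VERTICAL = "VERTICAL"
    #: grey level varies along the y (row) axis -> horizontal stripes
    HORIZONTAL = "HORIZONTAL"


@dataclass(frozen=True)
class TestPattern:
    """An 8-bit greyscale test image plus generation metadata."""

    pixels: np.ndarray
    kind: PatternKind
    frequency_index: int | None = None
    period_px: int | None = None
    orientation: Orientation = Orientation.VERTICAL
    radius_fraction: float | None = field(default=None)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.uint8)
        if px.ndim != 2:
            raise InvalidArgumentError("pattern pixels must be a 2-D array")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def metadata(self) -> dict:
        return {
            "kind": self.kind.value,
            "frequency_index": self.frequency_index,
            "period_px": self.period_px,
            "orientation": self.orientation.value,
            "radius_fraction": self.radius_fraction,
        }

    def save(self, png_path: str | Path) -> None:
        """Write the image as 8-bit greyscale PNG plus a JSON sidecar."""
        png_path = Path(png_path)
        Image.fromarray(self.pixels, mode="L").save(png_path)
        sidecar = png_path.with_suffix(".json")
        sidecar.write_text(json.dumps(self.metadata(), sort_keys=True, indent=1))


def load_pattern(png_path: str | Path) -> TestPattern:
    """Read a pattern written by :meth:`TestPattern.save`."""
    png_path = Path(png_path)
    pixels = np.asarray(Image.open(png_path).convert("L"), dtype=np.uint8)
    meta = json.loads(png_path.with_suffix(".json").read_text())
    return TestPattern(
        pixels=pixels,
        kind=PatternKind(meta["kind"]),
        frequency_index=meta.get("frequency_index"),
        period_px=meta.get("period_px"),
        orientation=Orientation(meta.get("orientation", "VERTICAL")),
        radius_fraction=meta.get("radius_fraction"),
    )


def line_period(frequency_index: int, image_size: int) -> int:
    """Line period in pixels for one of the seven spatial frequencies.

    Even by construction (so half-periods are integral) and clamped to >= 2.
    """
    if not isinstance(frequency_index, (int, np.integer)):
        raise InvalidArgumentError("frequency_index must be an integer")
    if not 0 <= frequency_index < N_LINE_FREQUENCIES:
        raise InvalidArgumentError(
            f"frequency_index must be in 0..{N_LINE_FREQUENCIES - 1}, "
            f"got {frequency_index}"
        )
    raw = image_size / (4.0 * 2.0 ** (frequency_index / 2.0))
    return max(2, 2 * int(round(raw / 2.0)))


def generate_line_pattern(
    frequency_index: int,
    image_size: int,
    orientation: Orientation = Orientation.VERTICAL,
) -> TestPattern:
    """Binary black/white line pattern at one of seven spatial frequencies."""
    period = line_period(frequency_index, image_size)
    if image_size < 2 * period:
        raise InvalidArgumentError(
            f"image_size {image_size} too small for period {period}"
        )
    half = period // 2
    axis = np.arange(image_size)
    profile = np.where((axis % period) < half, WHITE, BLACK).astype(np.uint8)
    if orientation is Orientation.VERTICAL:
        pixels = np.tile(profile, (image_size, 1))
    else:
        pixels = np.tile(profile[:, None], (1, image_size))
    return TestPattern(
        pixels=pixels,
        kind=PatternKind.LINES,
        frequency_index=int(frequency_index),
        period_px=period,
        orientation=orientation,
    )


def generate_roi_pattern(
    image_size: int,
    radius_fraction: float = DEFAULT_RADIUS_FRACTION,
) -> TestPattern:
    """White disc on black, centred; defines the region of interest."""
    if not 0.0 < radius_fraction <= 1.0:
        raise InvalidArgumentError(
            f"radius_fraction must be in (0, 1], got {radius_fraction}"
        )
    center = (image_size - 1) / 2.0
    radius = radius_fraction * image_size / 2.0
    yy, xx = np.ogrid[:image_size, :image_size]
    inside = (yy - center) ** 2 + (xx - center) ** 2 <= radius**2
    pixels = np.where(inside, WHITE, BLACK).astype(np.uint8)
    return TestPattern(
        pixels=pixels,
        kind=PatternKind.ROI_CIRCLE,
        radius_fraction=radius_fraction,
    )


def default_pattern_suite(
    image_size: int,
    orientation: Orientation = Orientation.VERTICAL,
    radius_fraction: float = DEFAULT_RADIUS_FRACTION,
) -> list[TestPattern]:
    """The bench's pattern suite: 7 line patterns (coarse to fine) then the ROI disc.

    Raises if ``image_size`` is too small for the seven periods to be
    strictly decreasing.
    """
    periods = [line_period(i, image_size) for i in range(N_LINE_FREQUENCIES)]
    if any(b >= a for a, b in zip(periods, periods[1:])):
        raise InvalidArgumentError(
            f"image_size {image_size} too small: line periods {periods} "
            "are not strictly decreasing"
        )
    suite = [
        generate_line_pattern(i, image_size, orientation)
        for i in range(N_LINE_FREQUENCIES)
    ]
    suite.append(generate_roi_pattern(image_size, radius_fraction))
    return suite
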