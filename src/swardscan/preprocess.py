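"""Noise filtering and invalid-return handling.

Raw line-scan LiDAR height profiles carry single-sample speckle noise and
no-return gaps.  Before plot segmentation each stream is (a) rectified from
polar range/angle readings to Cartesian heights if it arrived raw, (b)
smoothed with a moving average *along the lateral axis of each scan line*
(one scan = one line, so "the direction of the scan" is within-line), and
(c) stripped of invalid returns, which are excluded — never interpolated —
so the per-scan integrals stay strictly data-driven.

The moving average is NaN-aware: invalid samples neither contribute to nor
receive smoothed values, and windows truncate at the swath edges rather
than padding with invented data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

from .errors import ParameterError
from .scanio import ScanLine, ScanStream


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for one filtering pass."""

    n_invalid_removed: int
    window_used: int
    lines_touched: int

    def __post_init__(self) -> None:
        if min(self.n_invalid_removed, self.window_used,
               self.lines_touched) < 0:
            raise ParameterError("FilterReport counts must be >= 0")


def polar_to_heights(ranges_mm: np.ndarray, angles_rad: np.ndarray,
                     sensor_height_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Rectify raw polar returns to (lateral, height) coordinates.

    Angles are measured from nadir; a zero or negative range means no usable
    return and maps to an invalid (NaN) height.

    Returns ``(lateral_mm, height_mm)`` with
    ``lateral = r sin(theta)`` and ``height = sensor_height - r cos(theta)``.
    """
    ranges_mm = np.asarray(ranges_mm, dtype=float)
    angles_rad = np.asarray(angles_rad, dtype=float)
    if ranges_mm.shape != angles_rad.shape:
        raise ParameterError(
            f"ranges ({ranges_mm.shape}) and angles ({angles_rad.shape}) "
            "must have equal length")
    lateral = ranges_mm * np.sin(angles_rad)
    height = sensor_height_mm - ranges_mm * np.cos(angles_rad)
    bad = ranges_mm <= 0
    height = np.where(bad, np.nan, height)
    return lateral, height


def moving_average_heights(heights: np.ndarray, window: int) -> np.ndarray:
    """NaN-aware centered moving mean along the last axis.

    Each valid height becomes the mean of valid heights inside the centered
    window; windows truncate at the ends; NaN stays NaN.  Accepts a single
    line ``(n,)`` or a full stream ``(n_lines, n)``.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    heights = np.asarray(heights, dtype=float)
    if window == 1:
        return heights.copy()
    valid = np.isfinite(heights)
    kernel = np.ones(window)
    num = convolve1d(np.where(valid, heights, 0.0), kernel, axis=-1,
                     mode="constant", cval=0.0)
    cnt = convolve1d(valid.astype(float), kernel, axis=-1,
                     mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / cnt
    out[~valid] = np.nan
    return out


def moving_average(line: ScanLine, window: int) -> ScanLine:
    """Smooth one scan line laterally (see :func:`moving_average_heights`)."""
    return ScanLine(line.index, line.odometer_mm, line.lateral_mm,
                    moving_average_heights(line.heights_mm, window))


def drop_invalid(line: ScanLine) -> tuple[ScanLine, FilterReport]:
    """Flag invalid returns on a line; the lateral grid is retained.

    Invalid samples stay NaN in place (positions matter for integration
    gaps) but are guaranteed excluded from every downstream integral.
    A line with no valid sample at all is the degenerate "empty line":
    downstream plot integration treats it as zero evidence, not zero area.
    """
    n_invalid = int((~np.isfinite(line.heights_mm)).sum())
    report = FilterReport(n_invalid_removed=n_invalid, window_used=1,
                          lines_touched=1 if n_invalid else 0)
    return line, report


def is_empty_line(line: ScanLine) -> bool:
    """True when every sample on the line is invalid."""
    return line.n_valid == 0


def preprocess_stream(stream: ScanStream,
                      ma_window: int) -> tuple[ScanStream, FilterReport]:
    """Smooth every line of a stream and count invalid returns.

    Returns the filtered stream plus a report aggregated over all lines.
    """
    smoothed = moving_average_heights(stream.heights_mm, ma_window)
    invalid = ~np.isfinite(stream.heights_mm)
    report = FilterReport(
        n_invalid_removed=int(invalid.sum()),
        window_used=ma_window,
        lines_touched=int(invalid.any(axis=1).sum()),
    )
    out = ScanStream(stream.lateral_mm.copy(), stream.odometer_mm.copy(),
                     smoothed, stream.datum_note, dict(stream.meta))
    return out, report
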