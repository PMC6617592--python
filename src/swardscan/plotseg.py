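"""Plot segmentation, ground estimation and virtual-cut height extraction.

A scanned column is divided into fixed-length plot windows (half-open
along-track intervals, so no boundary scan is counted twice).  The soil
surface elevation is estimated *per plot* — ground level varies
substantially along a field column — as a low quantile of the plot's valid
heights: inter-row soil and canopy gaps populate the low tail, making the
estimate robust to canopy dominance.  Vegetation is then segmented from
soil by height: every sample is reduced to its height above an
operator-supplied virtual cutting height over the estimated ground,
clamped at zero, mimicking the residual left by mechanical defoliation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import CoverageError, EmptyPlotError, GeometryError
from .scanio import FieldConfig, ScanStream

#: Fraction of the nominal window length that must be covered by scans for a
#: plot to be considered fully populated; below this the plot is flagged
#: sparse (its LV is still computed from the observed span).
SPARSE_COVERAGE = 0.5

#: Odometer-drift tolerance: a stream may be up to 5% shorter than the
#: configured scan length before segmentation refuses to proceed.
SPAN_TOLERANCE = 0.95


@dataclass(frozen=True)
class PlotWindow:
    """One plot's half-open along-track interval [start_mm, end_mm)."""

    plot_id: str
    start_mm: float
    end_mm: float
    manual_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        if not self.end_mm > self.start_mm:
            raise GeometryError(
                f"plot {self.plot_id}: end_mm ({self.end_mm}) must exceed "
                f"start_mm ({self.start_mm})")

    @property
    def length_mm(self) -> float:
        return self.end_mm - self.start_mm

    def contains(self, odometer_mm: np.ndarray) -> np.ndarray:
        return (odometer_mm >= self.start_mm) & (odometer_mm < self.end_mm)


@dataclass
class PlotHeights:
    """One plot's scans reduced to heights above the virtual cut.

    ``h_plus`` holds max(height − ground − cut, 0) per sample, NaN where the
    return was invalid; rows align with ``odometer_mm``, columns with
    ``lateral_mm``.
    """

    window: PlotWindow
    ground_mm: float
    odometer_mm: np.ndarray
    lateral_mm: np.ndarray
    h_plus: np.ndarray
    status: str = "ok"  # ok | sparse | empty
    cutting_height_mm: float = 0.0

    @property
    def n_lines(self) -> int:
        return self.odometer_mm.size


def segment_column(stream: ScanStream, config: FieldConfig,
                   column_id: str = "col0") -> list[PlotWindow]:
    """Tile a column into equal plot windows from the first odometer position.

    Produces ``segments_per_scan`` windows of ``segment_length_mm`` each,
    covering [first_odometer, first_odometer + scan_length_mm).  Raises
    :class:`CoverageError` when the stream span falls short of the
    configured scan length by more than the drift tolerance.
    """
    span = stream.span_mm
    if span < config.scan_length_mm * SPAN_TOLERANCE:
        raise CoverageError(
            f"column {column_id}: stream spans {span:.0f} mm but the "
            f"configuration expects {config.scan_length_mm:.0f} mm "
            f"(shortfall {config.scan_length_mm - span:.0f} mm)")
    start = float(stream.odometer_mm[0])
    seg = config.segment_length_mm
    return [
        PlotWindow(plot_id=f"{column_id}_p{i + 1:02d}",
                   start_mm=start + i * seg, end_mm=start + (i + 1) * seg)
        for i in range(config.segments_per_scan)
    ]


def apply_manual_offsets(windows: Sequence[PlotWindow],
                         offsets: Mapping[str, float]) -> list[PlotWindow]:
    """Shift windows by per-plot manual alignment corrections.

    Offsets are keyed by plot_id; missing plots keep zero offset.  The
    shifted windows must remain disjoint and ordered, otherwise a
    :class:`GeometryError` names the colliding plots.
    """
    shifted = []
    for w in windows:
        off = float(offsets.get(w.plot_id, 0.0))
        shifted.append(replace(w, start_mm=w.start_mm + off,
                               end_mm=w.end_mm + off,
                               manual_offset_mm=w.manual_offset_mm + off))
    for a, b in zip(shifted, shifted[1:]):
        if b.start_mm < a.end_mm:
            raise GeometryError(
                f"manual offsets make plots {a.plot_id} and {b.plot_id} "
                f"overlap ([{a.start_mm}, {a.end_mm}) vs "
                f"[{b.start_mm}, {b.end_mm}))")
    return shifted


def estimate_ground(heights: np.ndarray, ground_percentile: float) -> float:
    """Ground elevation as a low quantile of valid in-window heights.

    Uses the linearly interpolated quantile of all finite height samples in
    the window (default 5th percentile upstream).  Raises
    :class:`EmptyPlotError` when the window holds no valid sample.
    """
    vals = np.asarray(heights, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise EmptyPlotError("no valid height samples in window")
    return float(np.quantile(vals, ground_percentile))


def heights_above_cut(window: PlotWindow, odometer_mm: np.ndarray,
                      lateral_mm: np.ndarray, heights: np.ndarray,
                      ground_mm: float,
                      cutting_height_mm: float) -> PlotHeights:
    """Reduce in-window heights to canopy height above the virtual cut.

    Per valid sample: h+ = max(height − ground − cut, 0); invalid samples
    stay NaN and contribute nothing downstream.
    """
    h = np.asarray(heights, dtype=float)
    h_plus = np.maximum(h - ground_mm - cutting_height_mm, 0.0)
    # NaN propagates through the arithmetic above, preserving invalid marks.
    return PlotHeights(window=window, ground_mm=ground_mm,
                       odometer_mm=np.asarray(odometer_mm, dtype=float),
                       lateral_mm=np.asarray(lateral_mm, dtype=float),
                       h_plus=h_plus, cutting_height_mm=cutting_height_mm)


def extract_plot(stream: ScanStream, window: PlotWindow,
                 config: FieldConfig) -> PlotHeights:
    """Select a window's scans, estimate its ground, and apply the cut.

    An empty window (no scans, or only invalid returns) yields a flagged
    ``status='empty'`` result rather than LV = 0, mirroring the manual
    correction workflow for sparsely populated plots; silently zeroed plots
    would corrupt downstream regressions.
    """
    mask = window.contains(stream.odometer_mm)
    odo = stream.odometer_mm[mask]
    heights = stream.heights_mm[mask]
    if odo.size == 0 or not np.isfinite(heights).any():
        return PlotHeights(window=window, ground_mm=np.nan,
                           odometer_mm=odo, lateral_mm=stream.lateral_mm,
                           h_plus=heights.copy(), status="empty",
                           cutting_height_mm=config.cutting_height_mm)
    ground = estimate_ground(heights, config.ground_percentile)
    ph = heights_above_cut(window, odo, stream.lateral_mm, heights, ground,
                           config.cutting_height_mm)
    coverage = (odo.max() - odo.min()) / window.length_mm
    if coverage < SPARSE_COVERAGE:
        ph.status = "sparse"
    return ph
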