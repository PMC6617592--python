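"""End-to-end orchestration: stream -> filtered -> plots -> LV results.

This is the library-level driver behind the command-line tool: it runs
filtering, segmentation, ground estimation, virtual-cut segmentation and
LV computation over one or more scanned columns, and records what happened
in a machine-readable run manifest (config snapshot, inputs, seed,
per-plot status) kept separate from the data outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .plotseg import apply_manual_offsets, extract_plot, segment_column
from .preprocess import preprocess_stream
from .scanio import FieldConfig, ScanStream
from .volumetrics import LVResult, compute_plot_lv


@dataclass
class RunManifest:
    """Reproducibility record for one processing run."""

    config: dict
    inputs: list[str] = field(default_factory=list)
    seed: int | None = None
    version: str = __version__
    plot_status: dict[str, str] = field(default_factory=dict)
    filter_reports: dict[str, dict] = field(default_factory=dict)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True)
                        + "\n")
        return path


def process_stream(stream: ScanStream, config: FieldConfig,
                   offsets: Mapping[str, float] | None = None,
                   column_id: str = "col0",
                   manifest: RunManifest | None = None,
                   reverse_plot_order: bool = False) -> list[LVResult]:
    """Process one scanned column into per-plot LV results.

    Steps: lateral moving-average filtering, window tiling, optional manual
    offsets, per-plot ground estimation and virtual-cut reduction, LV.
    ``reverse_plot_order`` renumbers plots back-to-front for up-column
    serpentine passes so plot ids match the planting order.
    """
    filtered, report = preprocess_stream(stream, config.ma_window)
    windows = segment_column(filtered, config, column_id=column_id)
    if reverse_plot_order or stream.meta.get("direction") == "reversed":
        ids = [w.plot_id for w in windows][::-1]
        windows = [
            type(w)(plot_id=pid, start_mm=w.start_mm, end_mm=w.end_mm,
                    manual_offset_mm=w.manual_offset_mm)
            for w, pid in zip(windows, ids)
        ]
    if offsets:
        windows = apply_manual_offsets(windows, offsets)
    results = []
    for w in windows:
        plot = extract_plot(filtered, w, config)
        res = compute_plot_lv(plot, lv_scale=config.lv_scale,
                              column_id=column_id)
        results.append(res)
        if manifest is not None:
            status = res.status
            if w.manual_offset_mm:
                status += "+manual-offset"
            manifest.plot_status[res.plot_id] = status
    if manifest is not None:
        manifest.filter_reports[column_id] = {
            "n_invalid_removed": report.n_invalid_removed,
            "window_used": report.window_used,
            "lines_touched": report.lines_touched,
        }
    return results


def process_files(paths: Sequence[str | Path], config: FieldConfig,
                  offsets: Mapping[str, float] | None = None,
                  manifest: RunManifest | None = None) -> list[LVResult]:
    """Process several column files; column ids derive from file stems."""
    from .scanio import read_scan_text

    results: list[LVResult] = []
    for path in paths:
        stream = read_scan_text(path)
        column_id = stream.meta.get("column_id", Path(path).stem)
        if manifest is not None:
            manifest.inputs.append(str(path))
        results.extend(process_stream(stream, config, offsets=offsets,
                                      column_id=column_id,
                                      manifest=manifest))
    return results
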