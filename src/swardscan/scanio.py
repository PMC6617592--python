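"""Reading and writing scan streams, trait tables and result files.

A *scan stream* is the raw record of a line-scanning LiDAR pass over one
column of row plots: an ordered sequence of scan lines, each holding an
along-track odometer position and a fixed lateral grid of height samples.
Heights are stored rectified (mm above the stream's datum), not as raw
ranges; samples with no signal return carry an INVALID marker.

On disk a stream is a self-describing whitespace-separated text file:

    # swardscan-stream v1
    # samples: 3
    # lateral_mm: -100.0 0.0 100.0
    # datum: wheel-plane
    # meta: scan_rate_hz=300 speed_mm_s=500
    0 0.0 12.3 45.6 NA
    1 1.7 12.1 44.9 13.0

Body rows are ``index odometer_mm h_1 ... h_n`` with ``NA`` marking an
invalid (no-return) sample.  Heights are written to 0.1 mm precision.
In memory INVALID is represented as NaN.

All coordinates are millimetres: x along travel, y lateral, z up.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, GeometryError, ParameterError

MAGIC = "swardscan-stream v1"
#: On-disk token for a no-return sample.
INVALID_TOKEN = "NA"
#: Decimal places kept for heights on disk (0.1 mm).
HEIGHT_DECIMALS = 1

RESULT_COLUMNS = [
    "plot_id", "column_id", "n_scans", "distance_mm", "ground_mm", "lv",
    "coverage_fraction", "status",
]


@dataclass(frozen=True)
class ScanLine:
    """A single scanner emission: one lateral height profile.

    ``heights_mm`` is aligned with ``lateral_mm``; NaN marks invalid samples.
    """

    index: int
    odometer_mm: float
    lateral_mm: np.ndarray
    heights_mm: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.heights_mm)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class ScanStream:
    """An ordered stack of scan lines sharing one lateral grid.

    Attributes
    ----------
    lateral_mm
        Strictly increasing lateral sample positions, shape ``(n_samples,)``.
    odometer_mm
        Non-decreasing along-track positions, shape ``(n_lines,)``.
    heights_mm
        Height matrix ``(n_lines, n_samples)``; NaN = invalid return.
    datum_note
        Free text describing the height datum.
    meta
        Header key-value pairs (scan rate, platform speed, point density...).
    """

    lateral_mm: np.ndarray
    odometer_mm: np.ndarray
    heights_mm: np.ndarray
    datum_note: str = ""
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lateral_mm = np.asarray(self.lateral_mm, dtype=float)
        self.odometer_mm = np.asarray(self.odometer_mm, dtype=float)
        self.heights_mm = np.asarray(self.heights_mm, dtype=float)
        self.validate()

    # -- geometry ---------------------------------------------------------
    def validate(self) -> None:
        if self.heights_mm.ndim != 2:
            raise FormatError("heights_mm must be 2-D (lines x samples)")
        n_lines, n_samples = self.heights_mm.shape
        if n_lines < 1:
            raise FormatError("a stream needs at least one scan line")
        if self.lateral_mm.shape != (n_samples,):
            raise FormatError(
                f"lateral grid has {self.lateral_mm.size} positions for "
                f"{n_samples} samples per line"
            )
        if self.odometer_mm.shape != (n_lines,):
            raise FormatError("odometer vector length != number of lines")
        if n_samples >= 2 and not np.all(np.diff(self.lateral_mm) > 0):
            raise GeometryError("lateral_mm must be strictly increasing")
        if np.any(np.diff(self.odometer_mm) < 0):
            raise GeometryError("odometer_mm must be non-decreasing")

    @property
    def n_lines(self) -> int:
        return self.heights_mm.shape[0]

    @property
    def n_samples(self) -> int:
        return self.heights_mm.shape[1]

    @property
    def span_mm(self) -> float:
        """Along-track extent: last odometer minus first."""
        return float(self.odometer_mm[-1] - self.odometer_mm[0])

    def line(self, i: int) -> ScanLine:
        return ScanLine(i, float(self.odometer_mm[i]), self.lateral_mm,
                        self.heights_mm[i])

    def __iter__(self):
        return (self.line(i) for i in range(self.n_lines))

    def reversed(self) -> "ScanStream":
        """Line order flipped — used to normalise up-column serpentine passes."""
        return ScanStream(self.lateral_mm.copy(), self.odometer_mm[::-1].copy(),
                          self.heights_mm[::-1].copy(), self.datum_note,
                          dict(self.meta))


def _normalize_direction(odometer: np.ndarray, rows: list[np.ndarray],
                         indices: list[int], meta: dict[str, str],
                         where: str) -> tuple[np.ndarray, list[np.ndarray]]:
    """Normalise an up-column serpentine pass to increasing odometer.

    A reversed pass records a non-increasing odometer; its lines are flipped
    so every in-memory stream runs in increasing x.  A genuinely non-monotone
    odometer is a geometry error.
    """
    d = np.diff(odometer)
    if np.any(d < 0):
        if np.all(d <= 0):
            meta.setdefault("direction", "reversed")
            return odometer[::-1], rows[::-1]
        bad = indices[int(np.argmax(d < 0)) + 1]
        raise GeometryError(f"{where}: non-monotone odometer at line index {bad}")
    return odometer, rows


@dataclass(frozen=True)
class FieldConfig:
    """Processing parameters for one trial layout.

    Defaults mirror a 36 m column of eighteen 2 m paired-row plots on 550 mm
    row spacing with a 40 mm virtual cutting height.
    """

    scan_length_mm: float = 36_000.0
    segments_per_scan: int = 18
    row_spacing_mm: float = 550.0
    cutting_height_mm: float = 40.0
    ground_percentile: float = 0.05
    ma_window: int = 5
    grid_res_mm: float = 50.0
    lv_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scan_length_mm <= 0:
            raise ParameterError("scan_length_mm must be > 0")
        if self.segments_per_scan < 1:
            raise ParameterError("segments_per_scan must be >= 1")
        if self.cutting_height_mm < 0:
            raise ParameterError("cutting_height_mm must be >= 0")
        if not (0.0 < self.ground_percentile < 1.0):
            raise ParameterError("ground_percentile must lie in (0, 1)")
        if self.ma_window < 1 or self.ma_window % 2 == 0:
            raise ParameterError("ma_window must be an odd integer >= 1")
        if self.row_spacing_mm <= 0:
            raise ParameterError("row_spacing_mm must be > 0")
        if self.grid_res_mm <= 0:
            raise ParameterError("grid_res_mm must be > 0")
        seg = self.scan_length_mm / self.segments_per_scan
        if abs(seg - round(seg)) > 1e-9:
            raise ParameterError(
                f"segment length {seg:.6f} mm is not exact to the mm "
                f"({self.scan_length_mm} mm / {self.segments_per_scan})"
            )

    @property
    def segment_length_mm(self) -> float:
        return self.scan_length_mm / self.segments_per_scan

    @classmethod
    def from_file(cls, path: str | Path) -> "FieldConfig":
        """Load from a key-value (YAML mapping) file; unknown keys rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise FormatError(f"{path}: config must be a key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        kwargs = dict(raw)
        if "segments_per_scan" in kwargs:
            kwargs["segments_per_scan"] = int(kwargs["segments_per_scan"])
        if "ma_window" in kwargs:
            kwargs["ma_window"] = int(kwargs["ma_window"])
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# Scan-stream text dialect
# ---------------------------------------------------------------------------

def read_scan_text(path: str | Path) -> ScanStream:
    """Parse a scan-stream text file.

    Raises :class:`FormatError` (with offending line numbers) for malformed
    headers or ragged body rows, and :class:`GeometryError` for a
    non-monotone odometer or lateral grid.
    """
    path = Path(path)
    lateral: np.ndarray | None = None
    declared_samples: int | None = None
    datum = ""
    meta: dict[str, str] = {}
    indices: list[int] = []
    odo: list[float] = []
    rows: list[np.ndarray] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text:
                continue
            if text.startswith("#"):
                body = text.lstrip("#").strip()
                if body.startswith("samples:"):
                    declared_samples = int(body.split(":", 1)[1])
                elif body.startswith("lateral_mm:"):
                    lateral = np.array(
                        [float(t) for t in body.split(":", 1)[1].split()])
                elif body.startswith("datum:"):
                    datum = body.split(":", 1)[1].strip()
                elif body.startswith("meta:"):
                    for token in body.split(":", 1)[1].split():
                        if "=" not in token:
                            raise FormatError(
                                f"{path}:{lineno}: meta token {token!r} "
                                "is not key=value")
                        k, v = token.split("=", 1)
                        meta[k] = v
                continue
            tokens = text.split()
            if lateral is None or declared_samples is None:
                raise FormatError(
                    f"{path}:{lineno}: body row before 'samples:'/"
                    "'lateral_mm:' header")
            if len(tokens) != 2 + declared_samples:
                raise FormatError(
                    f"{path}:{lineno}: expected {2 + declared_samples} "
                    f"fields, got {len(tokens)} (ragged row)")
            try:
                indices.append(int(tokens[0]))
                odo.append(float(tokens[1]))
                rows.append(np.array(
                    [np.nan if t == INVALID_TOKEN else float(t)
                     for t in tokens[2:]]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc

    if lateral is None or declared_samples is None:
        raise FormatError(f"{path}: missing stream header")
    if lateral.size != declared_samples:
        raise FormatError(
            f"{path}: header declares {declared_samples} samples but "
            f"lateral grid has {lateral.size}")
    if not rows:
        raise FormatError(f"{path}: stream has no scan lines")
    odo_arr, rows = _normalize_direction(np.array(odo), rows, indices, meta,
                                         str(path))
    return ScanStream(lateral, odo_arr, np.vstack(rows),
                      datum_note=datum, meta=meta)


def write_scan_text(stream: ScanStream, path: str | Path) -> Path:
    """Write a stream in the text dialect (heights at 0.1 mm precision)."""
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# {MAGIC}\n")
    buf.write(f"# samples: {stream.n_samples}\n")
    buf.write("# lateral_mm: "
              + " ".join(format(v, ".3f") for v in stream.lateral_mm) + "\n")
    if stream.datum_note:
        buf.write(f"# datum: {stream.datum_note}\n")
    if stream.meta:
        buf.write("# meta: "
                  + " ".join(f"{k}={v}" for k, v in stream.meta.items())
                  + "\n")
    for line in stream:
        heights = " ".join(
            INVALID_TOKEN if not np.isfinite(h)
            else format(round(h, HEIGHT_DECIMALS), f".{HEIGHT_DECIMALS}f")
            for h in line.heights_mm)
        buf.write(f"{line.index} {line.odometer_mm:.3f} {heights}\n")
    path.write_text(buf.getvalue())
    return path


def export_xyz(stream: ScanStream) -> pd.DataFrame:
    """Flatten a stream to a point-cloud table.

    One row per *valid* sample with columns ``x_mm`` (odometer), ``y_mm``
    (lateral) and ``z_mm`` (height); invalid samples are omitted.  The
    result may be empty.
    """
    nl, ns = stream.heights_mm.shape
    x = np.repeat(stream.odometer_mm, ns)
    y = np.tile(stream.lateral_mm, nl)
    z = stream.heights_mm.ravel()
    keep = np.isfinite(z)
    return pd.DataFrame({"x_mm": x[keep], "y_mm": y[keep], "z_mm": z[keep]})


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a plot trait CSV; requires plot_id, fw_g and dw_g columns."""
    df = pd.read_csv(path)
    missing = {"plot_id", "fw_g", "dw_g"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: trait table missing columns {sorted(missing)}")
    return df


def read_offsets(path: str | Path) -> dict[str, float]:
    """Read manual plot alignment offsets (CSV: plot_id, offset_mm)."""
    df = pd.read_csv(path)
    missing = {"plot_id", "offset_mm"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: offsets file missing columns {sorted(missing)}")
    return dict(zip(df["plot_id"].astype(str), df["offset_mm"].astype(float)))


def write_results(results: Sequence, path: str | Path) -> Path:
    """Write LV results to CSV (one row per plot, fixed column order)."""
    records = []
    for r in results:
        records.append({
            "plot_id": r.plot_id, "column_id": r.column_id,
            "n_scans": r.n_scans, "distance_mm": r.distance_mm,
            "ground_mm": r.ground_mm, "lv": r.lv,
            "coverage_fraction": r.coverage_fraction, "status": r.status,
        })
    df = pd.DataFrame.from_records(records, columns=RESULT_COLUMNS)
    df.to_csv(path, index=False)
    return Path(path)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"plot_id", "lv"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: results table missing columns {sorted(missing)}")
    return df
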