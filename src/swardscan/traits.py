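"""Trait statistics downstream of the LiDAR Volume index.

Covers the analyses a forage trial runs on per-plot FW (fresh weight,
g/row), DW (dry weight, g/row) and LV values: dry-matter content
(%DM = DW/FW), coefficient of variation (CV = sigma/mu, sample SD),
relative growth rate (RGR = (ln Y2 - ln Y1)/(t2 - t1), per day), ordinary
least-squares regression of LV on yield with the X-intercept
(-intercept/slope), and the normalised covariance (Pearson correlation)
matrix across entry-level parameters.

A bundled example dataset — per-cultivar trait summaries and regression
parameters from a replicated 12-cultivar perennial ryegrass trial — is
provided for worked examples and cross-checks; note its %DM column is
printed as a fraction (0.28-0.34), so table-matching output rounds the
fraction to 2 decimals rather than reporting percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, SingularFitError


class PercentDM(NamedTuple):
    fraction: float
    percent: float


class CVSummary(NamedTuple):
    mean: float
    sd: float
    cv_percent: float


@dataclass(frozen=True)
class TraitRecord:
    """One entry's trait values."""

    entry_id: str
    fw_g: float
    dw_g: float
    pdm: float
    lv: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pdm <= 1.0):
            raise ParameterError("pdm must lie in [0, 1]")


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of y on x with the axis intercepts the trial reports."""

    slope: float
    y_intercept: float
    x_intercept: float
    r2: float
    n: int


@dataclass
class GrowthSeries:
    """An entry's (t, y) observations with per-interval growth rates."""

    entry_id: str
    t_days: np.ndarray
    y: np.ndarray
    rgr_per_day: np.ndarray       # one per interval
    pct_per_day: np.ndarray       # (y2/y1 - 1) * 100 / dt, one per interval


def percent_dm(fw_g: float, dw_g: float) -> PercentDM:
    """Dry-matter content of a harvested sample.

    Returns both the fraction DW/FW and its percent form.  DW cannot
    exceed FW (a dried sample only loses water).
    """
    if fw_g <= 0:
        raise ParameterError("fw_g must be > 0")
    if not (0.0 <= dw_g <= fw_g):
        raise ParameterError(
            f"dw_g ({dw_g}) must lie in [0, fw_g] (fw_g = {fw_g})")
    frac = dw_g / fw_g
    return PercentDM(fraction=frac, percent=100.0 * frac)


def coefficient_of_variation(values: Sequence[float]) -> CVSummary:
    """Mean, sample SD (n-1 denominator) and CV% of a trait vector."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ParameterError("CV needs at least 2 values")
    mean = float(v.mean())
    if mean == 0.0:
        raise ParameterError("CV undefined for zero mean")
    sd = float(v.std(ddof=1))
    return CVSummary(mean=mean, sd=sd, cv_percent=100.0 * sd / mean)


def relative_growth_rate(y1: float, y2: float, t1: float, t2: float) -> float:
    """RGR = (ln y2 - ln y1) / (t2 - t1), per day."""
    if y1 <= 0 or y2 <= 0:
        raise ParameterError("RGR needs positive yields")
    if t2 <= t1:
        raise ParameterError("RGR needs t2 > t1")
    return (math.log(y2) - math.log(y1)) / (t2 - t1)


def linear_fit(x_values: Sequence[float],
               y_values: Sequence[float]) -> RegressionFit:
    """OLS of y on x with R² and the X-intercept (-y_intercept / slope)."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if x.size < 2:
        raise SingularFitError("regression needs n >= 2")
    if np.ptp(x) == 0:
        raise SingularFitError("regression needs non-constant x")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    intercept = float(res.intercept)
    x_int = -intercept / slope if slope != 0 else math.nan
    return RegressionFit(slope=slope, y_intercept=intercept,
                         x_intercept=x_int, r2=float(res.rvalue ** 2),
                         n=int(x.size))


def growth_series(entry_id: str,
                  observations: Sequence[tuple[float, float]]) -> GrowthSeries:
    """Per-interval RGR and percent change per day for a yield time series.

    Contraction intervals (declining LV) are reported as negative rates,
    not suppressed.
    """
    if len(observations) < 2:
        raise ParameterError("growth series needs >= 2 observations")
    t = np.array([o[0] for o in observations], dtype=float)
    y = np.array([o[1] for o in observations], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ParameterError("observation times must be strictly increasing")
    rgr = np.array([
        relative_growth_rate(y[i], y[i + 1], t[i], t[i + 1])
        for i in range(t.size - 1)
    ])
    dt = np.diff(t)
    pct = (y[1:] / y[:-1] - 1.0) * 100.0 / dt
    return GrowthSeries(entry_id=entry_id, t_days=t, y=y, rgr_per_day=rgr,
                        pct_per_day=pct)


def normalized_covariance(table: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pearson correlation matrix of the columns, in [-1, 1].

    Zero-variance columns give undefined (NaN) entries, flagged rather
    than erroring, so one degenerate parameter does not sink the matrix.
    """
    if isinstance(table, pd.DataFrame):
        df = table.select_dtypes("number")
    else:
        arr = np.asarray(table, dtype=float)
        df = pd.DataFrame(arr, columns=[f"c{i}" for i in range(arr.shape[1])])
    if df.shape[0] < 2:
        raise ParameterError("correlation matrix needs >= 2 rows")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(df.to_numpy(), rowvar=False)
    corr = np.atleast_2d(corr)
    zero_var = df.std(ddof=1).to_numpy() == 0
    corr[zero_var, :] = np.nan
    corr[:, zero_var] = np.nan
    return pd.DataFrame(corr, index=df.columns, columns=df.columns)


# ---------------------------------------------------------------------------
# Bundled example dataset (12-cultivar ryegrass trial summaries)
# ---------------------------------------------------------------------------

def load_cultivar_traits() -> pd.DataFrame:
    """Per-cultivar FW/DW/%DM/LV summary of the bundled 12-cultivar trial."""
    with resources.files("swardscan.data").joinpath(
            "cultivar_traits.csv").open() as fh:
        return pd.read_csv(fh)


def load_cultivar_regressions() -> pd.DataFrame:
    """Per-cultivar LV-on-FW regression parameters of the bundled trial.

    The r2 value for cultivar 8 is not available in the source summary and
    is stored as NaN.
    """
    with resources.files("swardscan.data").joinpath(
            "cultivar_regression.csv").open() as fh:
        return pd.read_csv(fh)


def trial_summary(traits: pd.DataFrame,
                  columns: Sequence[str] = ("fw_g", "dw_g", "pdm", "lv"),
                  ) -> pd.DataFrame:
    """CV / sigma / mu rows for the requested trait columns."""
    out: dict[str, dict[str, float]] = {}
    for col in columns:
        cv = coefficient_of_variation(traits[col].to_numpy())
        out[col] = {"cv_percent": cv.cv_percent, "sd": cv.sd,
                    "mean": cv.mean}
    return pd.DataFrame(out)
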