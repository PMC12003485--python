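"""Seasonal and interannual aggregation: weather summaries, trends, and
the historical water-column table.

Meteorological series arrive at the station's native cadence (10 min).
Monthly summaries report mean ± sd air temperature, the time-integrated
net radiation (W m⁻² × interval seconds summed over the month, in
J m⁻²), and total rainfall; months with less than half their expected
records are flagged rather than dropped.  The interannual air-
temperature trend is an ordinary least-squares line through annual
means — a descriptive rate in °C per year, not a climate attribution.

The historical table condenses each cast into surface and bottom
temperature and κ20 (means over the shallowest 0.5 m and deepest 1 m),
the cast's Schmidt stability, and, where sulfide observations exist,
the mean bottom H₂S between 18 and 20 m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, SchemaError
from .profiles import CTDProfile
from .stability import StabilityResult

METEO_COLUMNS = ("temp_c", "netrad_wm2", "rain_mm", "wind_ms")


@dataclass
class MeteoSeries:
    """Timestamped weather records; rainfall is mm per native interval."""

    data: pd.DataFrame  # index: DatetimeIndex; columns ⊆ METEO_COLUMNS

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df.index, pd.DatetimeIndex):
            if "timestamp" in df.columns:
                df = df.set_index(pd.DatetimeIndex(df["timestamp"])
                                  ).drop(columns="timestamp")
            else:
                raise SchemaError("MeteoSeries needs a timestamp index")
        if df.index.has_duplicates or not df.index.is_monotonic_increasing:
            raise SchemaError("timestamps must be strictly increasing")
        if "rain_mm" in df.columns and (df["rain_mm"] < 0).any():
            raise SchemaError("rainfall must be >= 0")
        self.data = df

    @property
    def cadence(self) -> pd.Timedelta:
        """Native sampling interval (median spacing)."""
        if len(self.data) < 2:
            return pd.Timedelta(minutes=10)
        return pd.Timedelta(np.median(np.diff(self.data.index.values)))

    @classmethod
    def from_csv(cls, path) -> "MeteoSeries":
        return cls(pd.read_csv(path, parse_dates=["timestamp"]))

    def write_csv(self, path) -> None:
        self.data.rename_axis("timestamp").to_csv(path)


@dataclass(frozen=True)
class TrendFit:
    slope: float       # degC per year
    intercept: float   # degC at year 0 of the fit's origin
    n_years: int
    stderr: float


def monthly_summary(series: MeteoSeries) -> pd.DataFrame:
    """Per-calendar-month statistics of a weather series.

    Columns: ``temp_mean_c``/``temp_sd_c`` over native records,
    ``netrad_integral_J_m2`` = Σ(W m⁻² × interval s),
    ``rainfall_total_mm`` = Σ intervals, ``coverage`` fraction of
    expected records present, and ``low_coverage`` flag (< 50 %).
    Channels absent from the input are absent from the output.
    """
    df = series.data
    if not len(df):
        raise InsufficientDataError("empty meteorological series")
    dt_s = series.cadence.total_seconds()
    by = df.groupby(pd.PeriodIndex(df.index, freq="M"))

    out = pd.DataFrame(index=by.size().index)
    out.index.name = "month"
    if "temp_c" in df.columns:
        out["temp_mean_c"] = by["temp_c"].mean()
        out["temp_sd_c"] = by["temp_c"].std(ddof=1)
    if "netrad_wm2" in df.columns:
        out["netrad_integral_J_m2"] = by["netrad_wm2"].sum() * dt_s
    if "rain_mm" in df.columns:
        out["rainfall_total_mm"] = by["rain_mm"].sum()
    if "wind_ms" in df.columns:
        out["wind_mean_ms"] = by["wind_ms"].mean()

    expected = out.index.days_in_month * 86400 / dt_s
    out["coverage"] = by.size().to_numpy() / np.asarray(expected)
    out["low_coverage"] = out["coverage"] < 0.5
    return out


def resample_meteo(series: MeteoSeries, window: pd.Timedelta | str
                   ) -> MeteoSeries:
    """Block-average temperature/radiation/wind, block-sum rainfall.

    Blocks are aligned to the window start.  A running cumulative
    rainfall column (``rain_cum_mm``) is added when rainfall is present.
    """
    window = pd.Timedelta(window)
    if window < series.cadence:
        raise InsufficientDataError(
            f"window {window} shorter than native cadence {series.cadence}")
    df = series.data
    agg = {}
    for col in df.columns:
        agg[col] = "sum" if col == "rain_mm" else "mean"
    res = df.resample(window, origin="start").agg(agg)
    if "rain_mm" in res.columns:
        res["rain_cum_mm"] = res["rain_mm"].cumsum()
    return MeteoSeries(res)


def annual_trend(annual_means: Sequence[tuple[int, float]] | pd.DataFrame
                 ) -> TrendFit:
    """OLS line through (year, annual mean temperature) points.

    Order-invariant; at least three years required for a reported slope.
    """
    if isinstance(annual_means, pd.DataFrame):
        pairs = list(zip(annual_means.iloc[:, 0], annual_means.iloc[:, 1]))
    else:
        pairs = list(annual_means)
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"trend needs >= 3 years; got {len(pairs)}")
    years = np.array([p[0] for p in pairs], dtype=float)
    temps = np.array([p[1] for p in pairs], dtype=float)
    fit = stats.linregress(years, temps)
    return TrendFit(slope=float(fit.slope), intercept=float(fit.intercept),
                    n_years=len(pairs), stderr=float(fit.stderr))


def annual_means_from_meteo(series: MeteoSeries) -> list[tuple[int, float]]:
    """Annual mean air temperature, one pair per calendar year."""
    g = series.data["temp_c"].groupby(series.data.index.year).mean()
    return [(int(y), float(t)) for y, t in g.items()]


def _layer_mean(depth: np.ndarray, vals: np.ndarray | None,
                z0: float, z1: float) -> float:
    if vals is None:
        return np.nan
    sel = (depth >= z0) & (depth <= z1)
    return float(np.mean(vals[sel])) if sel.any() else np.nan


def historical_record_table(
    profiles: Iterable[CTDProfile],
    stability: dict[str, StabilityResult] | None = None,
    h2s_obs: pd.DataFrame | None = None,
    surface_window_m: float = 0.5,
    bottom_window_m: float = 1.0,
    h2s_depth_range: tuple[float, float] = (18.0, 20.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condense casts into per-cast records plus a yearly mean ± sd table.

    Surface values average the shallowest ``surface_window_m`` of each
    cast; bottom values the deepest ``bottom_window_m``.  ``stability``
    maps cast_id to that cast's :class:`StabilityResult`.  ``h2s_obs``,
    when given, has columns ``date``, ``depth_m``, ``h2s_mgL``; the
    bottom sulfide of a cast's date is the mean of observations within
    ``h2s_depth_range``.  Casts spanning less than 2 m are skipped.
    Returns ``(per_cast, per_year)``.
    """
    rows = []
    for p in profiles:
        z = p.depth
        if z[-1] - z[0] < 2.0:
            continue  # too shallow to define surface vs bottom
        zs0, zs1 = z[0], z[0] + surface_window_m
        zb0, zb1 = z[-1] - bottom_window_m, z[-1]
        rec = {
            "cast_id": p.cast_id,
            "date": p.timestamp,
            "surface_temp_c": _layer_mean(z, p.temperature, zs0, zs1),
            "bottom_temp_c": _layer_mean(z, p.temperature, zb0, zb1),
            "surface_k20_uScm": _layer_mean(z, p.k20, zs0, zs1),
            "bottom_k20_uScm": _layer_mean(z, p.k20, zb0, zb1),
        }
        if stability and p.cast_id in stability:
            rec["sc_kJ_m2"] = stability[p.cast_id].sc_kJ_m2
        else:
            rec["sc_kJ_m2"] = np.nan
        rec["bottom_h2s_mgL"] = np.nan
        if h2s_obs is not None and p.timestamp is not None:
            day = pd.Timestamp(p.timestamp).normalize()
            obs = h2s_obs[
                (pd.to_datetime(h2s_obs["date"]).dt.normalize() == day)
                & (h2s_obs["depth_m"] >= h2s_depth_range[0])
                & (h2s_obs["depth_m"] <= h2s_depth_range[1])]
            if len(obs):
                rec["bottom_h2s_mgL"] = float(obs["h2s_mgL"].mean())
        rows.append(rec)

    per_cast = pd.DataFrame(rows)
    if not len(per_cast):
        return per_cast, pd.DataFrame()
    per_cast = per_cast.sort_values("date", kind="stable"
                                    ).reset_index(drop=True)

    value_cols = [c for c in per_cast.columns
                  if c not in ("cast_id", "date")]
    years = pd.to_datetime(per_cast["date"]).dt.year
    per_year = per_cast.groupby(years)[value_cols].agg(["mean", "std"])
    per_year.index.name = "year"
    per_year.columns = [f"{c}_{s}" for c, s in per_year.columns]
    return per_cast, per_year
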