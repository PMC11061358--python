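"""Hourly thermal-time accounting for dormancy modelling.

Implements the three classic chill models used for temperate fruit trees —
Chilling Hours (Weinberger), Chilling Units (Utah) and Chilling Portions
(Dynamic model) — together with the Growing Degree Hours (GDH) heat model,
plus the supporting machinery: conversion of daily temperature extremes to
an idealized hourly curve and resampling of semi-hourly station records.

All models are driven by hourly temperatures in °C.  Per-hour contributions:

* CH: 1 for an hour in the 0–7.2 °C band, else 0.
* CU: piecewise weights; full credit on [2.5, 9.2), half credit on
  [1.5, 2.5) and [9.2, 12.5), zero on (−inf, 1.5) and [12.5, 16),
  −0.5 on [16, 18) and −1.0 at ≥ 18 °C.  Negative credit means warm hours
  cancel previously accumulated chill.
* CP: output of the two-step kinetic Dynamic model, in which a thermally
  labile intermediate accumulates at cold temperatures, is destroyed by
  warmth, and converts irreversibly to a "portion" once a unit threshold
  is reached.
* GDH: max(0, min(T, 25) − 4.5); one degree-hour above the 4.5 °C base,
  capped at the 25 °C optimum (maximum 20.5 GDH per hour).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DynamicModelConstants",
    "DynamicModelState",
    "HourlyTempSeries",
    "ChillProfile",
    "chilling_hours_hour",
    "utah_units_hour",
    "gdh_hour",
    "chilling_hours",
    "utah_units",
    "gdh",
    "dynamic_model_step",
    "dynamic_portions",
    "accumulate",
    "hourly_from_daily",
    "resample_semihourly",
    "daylength",
]

MODELS = ("CH", "CU", "CP", "GDH")

# Utah model breakpoints (°C) and the weight on each half-open band
# [b_i, b_{i+1}).  The printed band edges (9.1/9.2, 12.4/12.5, 15.9/16)
# leave 0.1 °C slivers; contiguous half-open intervals remove them while
# honouring every printed boundary.
_UTAH_BREAKS = np.array([1.5, 2.5, 9.2, 12.5, 16.0, 18.0])
_UTAH_WEIGHTS = np.array([0.0, 0.5, 1.0, 0.5, 0.0, -0.5, -1.0])

GDH_BASE_C = 4.5
GDH_CAP_C = 25.0
CH_LOW_C = 0.0
CH_HIGH_C = 7.2


def _check_finite(temp: float) -> float:
    temp = float(temp)
    if not math.isfinite(temp):
        raise ValueError(f"temperature must be finite, got {temp!r}")
    return temp


def chilling_hours_hour(temp_c: float) -> float:
    """Chilling Hours contribution of one hour at ``temp_c`` (0 or 1)."""
    temp_c = _check_finite(temp_c)
    return 1.0 if CH_LOW_C <= temp_c <= CH_HIGH_C else 0.0


def utah_units_hour(temp_c: float) -> float:
    """Utah-model Chilling Units contribution of one hour at ``temp_c``."""
    temp_c = _check_finite(temp_c)
    return float(_UTAH_WEIGHTS[np.searchsorted(_UTAH_BREAKS, temp_c, side="right")])


def gdh_hour(temp_c: float) -> float:
    """Growing Degree Hours contribution of one hour at ``temp_c``."""
    temp_c = _check_finite(temp_c)
    return max(0.0, min(temp_c, GDH_CAP_C) - GDH_BASE_C)


def _as_finite_array(temps_c) -> np.ndarray:
    arr = np.asarray(temps_c, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("temperatures must be finite")
    return arr


def chilling_hours(temps_c) -> np.ndarray:
    """Vectorized per-hour CH contributions."""
    arr = _as_finite_array(temps_c)
    return ((arr >= CH_LOW_C) & (arr <= CH_HIGH_C)).astype(float)


def utah_units(temps_c) -> np.ndarray:
    """Vectorized per-hour CU contributions."""
    arr = _as_finite_array(temps_c)
    return _UTAH_WEIGHTS[np.searchsorted(_UTAH_BREAKS, arr, side="right")]


def gdh(temps_c) -> np.ndarray:
    """Vectorized per-hour GDH contributions."""
    arr = _as_finite_array(temps_c)
    return np.clip(np.minimum(arr, GDH_CAP_C) - GDH_BASE_C, 0.0, None)


# ---------------------------------------------------------------------------
# Dynamic model
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class DynamicModelConstants:
    """Kinetic constants of the two-step Dynamic chill model.

    The defaults are the standard published parameterization used by the
    common chill-modelling toolchain.  ``slope`` and ``transition_k``
    (in kelvin) shape the temperature response of the conversion
    probability; ``a0``/``e0`` govern formation and ``a1``/``e1``
    destruction of the intermediate product.
    """

    slope: float = 1.6
    transition_k: float = 277.0
    a0: float = 1.395e5
    a1: float = 2.567e18
    e0: float = 4153.5
    e1: float = 12888.8

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if not math.isfinite(value):
                raise ValueError(f"dynamic-model constant {field.name} must be finite")


@dataclasses.dataclass
class DynamicModelState:
    """State of the Dynamic model between hourly steps.

    ``x`` is the level of the thermally labile intermediate (dimensionless);
    ``portions`` is the irreversibly accumulated chill in CP.
    """

    x: float = 0.0
    portions: float = 0.0
    constants: DynamicModelConstants = dataclasses.field(
        default_factory=DynamicModelConstants
    )

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError("intermediate level x must be nonnegative")
        if self.portions < 0:
            raise ValueError("portions must be nonnegative")


def dynamic_model_step(state: DynamicModelState, temp_c: float) -> DynamicModelState:
    """Advance the Dynamic model by one hour at ``temp_c``.

    The intermediate relaxes exponentially toward its temperature-dependent
    equilibrium; once it reaches the unit threshold, a temperature-dependent
    fraction converts irreversibly into portions and is removed from the
    intermediate pool.
    """
    temp_c = _check_finite(temp_c)
    c = state.constants
    tk = temp_c + 273.0
    ftmprt = c.slope * c.transition_k * (tk - c.transition_k) / tk
    sr = math.exp(ftmprt)
    xi = sr / (1.0 + sr)
    xs = c.a0 / c.a1 * math.exp(-(c.e0 - c.e1) / tk)
    ak1 = c.a1 * math.exp(-c.e1 / tk)
    x_new = xs - (xs - state.x) * math.exp(-ak1)
    if x_new >= 1.0:
        delta = xi * x_new
        x_carry = x_new - delta
    else:
        delta = 0.0
        x_carry = x_new
    return DynamicModelState(
        x=x_carry, portions=state.portions + delta, constants=c
    )


def dynamic_portions(
    temps_c,
    constants: DynamicModelConstants | None = None,
    initial: DynamicModelState | None = None,
):
    """Per-hour Dynamic-model portions for one or many hourly series.

    Parameters
    ----------
    temps_c : array-like, shape (n_hours,) or (n_series, n_hours)
        Hourly temperatures in °C.  A 2-D input runs the recursion for all
        series simultaneously (vectorized across the leading axis).
    constants : DynamicModelConstants, optional
    initial : DynamicModelState, optional
        Starting state (scalar); defaults to a fresh state (x = 0, 0 CP).

    Returns
    -------
    hourly : ndarray, same shape as input
        Portions converted at each hour (≥ 0; mostly 0 between conversions).
    final_x : ndarray
        Intermediate level after the last hour, per series.
    """
    arr = _as_finite_array(temps_c)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    c = constants or (initial.constants if initial is not None else DynamicModelConstants())
    n_series, n_hours = arr.shape

    tk = arr + 273.0
    ftmprt = c.slope * c.transition_k * (tk - c.transition_k) / tk
    sr = np.exp(ftmprt)
    xi = sr / (1.0 + sr)
    xs = c.a0 / c.a1 * np.exp(-(c.e0 - c.e1) / tk)
    decay = np.exp(-c.a1 * np.exp(-c.e1 / tk))

    x = np.full(n_series, initial.x if initial is not None else 0.0)
    hourly = np.zeros_like(arr)
    for h in range(n_hours):
        x = xs[:, h] - (xs[:, h] - x) * decay[:, h]
        converting = x >= 1.0
        delta = np.where(converting, xi[:, h] * x, 0.0)
        x = x - delta
        hourly[:, h] = delta
    if squeeze:
        return hourly[0], x[0]
    return hourly, x


# ---------------------------------------------------------------------------
# Hourly series container
# ---------------------------------------------------------------------------


class HourlyTempSeries:
    """Ordered hourly temperatures (°C) for one station.

    Wraps a :class:`pandas.Series` with a strictly increasing hourly
    ``DatetimeIndex`` (local standard time, no DST) and carries the station
    id and latitude needed by the solar-geometry day-curve.
    """

    def __init__(
        self,
        temps: pd.Series,
        station_id: str = "station",
        latitude: float = 40.0,
    ) -> None:
        if not isinstance(temps.index, pd.DatetimeIndex):
            raise TypeError("temps must be indexed by a DatetimeIndex")
        if len(temps) == 0:
            raise ValueError("empty temperature series")
        diffs = np.diff(temps.index.asi8)
        if len(diffs) and not np.all(diffs == 3_600_000_000_000):
            raise ValueError("timestamps must be strictly increasing at 1 h spacing")
        values = temps.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("temperatures must be finite")
        self.temps = temps.astype(float)
        self.temps.name = "temp_c"
        self.station_id = str(station_id)
        self.latitude = float(latitude)

    def __len__(self) -> int:
        return len(self.temps)

    def __repr__(self) -> str:
        return (
            f"HourlyTempSeries(station={self.station_id!r}, n={len(self)}, "
            f"{self.temps.index[0]} … {self.temps.index[-1]})"
        )

    @property
    def start(self) -> pd.Timestamp:
        return self.temps.index[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.temps.index[-1]

    def window(self, start_date, end_date) -> pd.Series:
        """Hourly values from ``start_date`` 00:00 through ``end_date`` 23:00.

        Raises ``ValueError`` listing the missing span if not fully covered.
        An empty window (start after end) returns an empty series.
        """
        start = pd.Timestamp(start_date)
        end = pd.Timestamp(end_date) + pd.Timedelta(hours=23)
        if start > end:
            return self.temps.iloc[0:0]
        if start < self.start or end > self.end:
            raise ValueError(
                f"series covers {self.start}–{self.end}; window "
                f"{start}–{end} not covered"
            )
        return self.temps.loc[start:end]


@dataclasses.dataclass
class ChillProfile:
    """Hourly and cumulative thermal-time trajectories over a window.

    ``frame`` holds one row per hour with ``<model>_hourly`` and
    ``<model>_cum`` columns; ``totals`` the window totals; ``final_state``
    the Dynamic-model state at the window end (present when CP requested),
    allowing continuation across windows.
    """

    frame: pd.DataFrame
    totals: dict
    start: pd.Timestamp
    end: pd.Timestamp
    final_state: DynamicModelState | None = None

    def to_tidy(self) -> pd.DataFrame:
        """Long-format export: (timestamp, model, hourly, cumulative)."""
        rows = []
        for model in MODELS:
            col = f"{model}_hourly"
            if col in self.frame:
                rows.append(
                    pd.DataFrame(
                        {
                            "timestamp": self.frame.index,
                            "model": model,
                            "hourly": self.frame[col].to_numpy(),
                            "cumulative": self.frame[f"{model}_cum"].to_numpy(),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def accumulate(
    series: HourlyTempSeries,
    start_date,
    end_date,
    models: Sequence[str] = MODELS,
    initial_state: DynamicModelState | None = None,
    constants: DynamicModelConstants | None = None,
    clamp_cu: bool = False,
) -> ChillProfile:
    """Accumulate the requested thermal-time models over a date window.

    The window runs from hour 0 of ``start_date`` through hour 23 of
    ``end_date`` (both inclusive).  Cumulative CU is not clamped at zero
    unless ``clamp_cu`` is set.  ``initial_state`` carries the Dynamic-model
    intermediate across windows so split accumulations match a single pass.
    """
    models = tuple(models)
    unknown = set(models) - set(MODELS)
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    window = series.window(start_date, end_date)
    temps = window.to_numpy(dtype=float)
    frame = pd.DataFrame(index=window.index)
    totals: dict = {}
    final_state = None
    if "CH" in models:
        frame["CH_hourly"] = chilling_hours(temps) if len(temps) else []
        frame["CH_cum"] = frame["CH_hourly"].cumsum()
        totals["CH"] = float(frame["CH_hourly"].sum())
    if "CU" in models:
        frame["CU_hourly"] = utah_units(temps) if len(temps) else []
        cum = frame["CU_hourly"].cumsum()
        if clamp_cu and len(cum):
            running, total = [], 0.0
            for v in frame["CU_hourly"]:
                total = max(0.0, total + v)
                running.append(total)
            cum = pd.Series(running, index=frame.index)
        frame["CU_cum"] = cum
        totals["CU"] = float(cum.iloc[-1]) if len(cum) else 0.0
    if "CP" in models:
        if len(temps):
            hourly, final_x = dynamic_portions(
                temps, constants=constants, initial=initial_state
            )
            base = initial_state.portions if initial_state is not None else 0.0
            frame["CP_hourly"] = hourly
            frame["CP_cum"] = base + np.cumsum(hourly)
            totals["CP"] = float(np.sum(hourly))
            final_state = DynamicModelState(
                x=float(final_x),
                portions=base + totals["CP"],
                constants=constants
                or (initial_state.constants if initial_state else DynamicModelConstants()),
            )
        else:
            frame["CP_hourly"] = []
            frame["CP_cum"] = []
            totals["CP"] = 0.0
            final_state = initial_state or DynamicModelState(constants=constants or DynamicModelConstants())
    if "GDH" in models:
        frame["GDH_hourly"] = gdh(temps) if len(temps) else []
        frame["GDH_cum"] = frame["GDH_hourly"].cumsum()
        totals["GDH"] = float(frame["GDH_hourly"].sum())
    return ChillProfile(
        frame=frame,
        totals=totals,
        start=pd.Timestamp(start_date),
        end=pd.Timestamp(end_date),
        final_state=final_state,
    )


# ---------------------------------------------------------------------------
# Daily extremes → hourly curve
# ---------------------------------------------------------------------------


def daylength(latitude: float, day_of_year) -> np.ndarray:
    """Daylength in hours from standard solar geometry.

    Uses the Cooper declination formula; polar clipping applies outside
    ±66° latitude, which is why callers restrict latitude to [−66, 66].
    """
    j = np.asarray(day_of_year, dtype=float)
    decl = np.deg2rad(23.45) * np.sin(2.0 * np.pi * (284.0 + j) / 365.0)
    phi = np.deg2rad(latitude)
    cos_h0 = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    return 2.0 * np.rad2deg(np.arccos(cos_h0)) / 15.0


def hourly_from_daily(
    daily: pd.DataFrame,
    latitude: float,
    station_id: str = "station",
) -> HourlyTempSeries:
    """Idealized hourly temperatures from daily extremes.

    ``daily`` needs columns ``date``, ``tmin_c``, ``tmax_c`` (or a
    DatetimeIndex plus the two temperature columns).  The day-curve rises
    as a quarter sine from the minimum at sunrise to the maximum in early
    afternoon, then decays logarithmically through the night to the next
    day's minimum at the following sunrise.  Sunrise and time-of-maximum
    are snapped to the hourly grid, and each day's 24 sampled values are
    affinely rescaled so the sampled extremes reproduce that day's
    Tmin/Tmax exactly.
    """
    if not (-66.0 <= latitude <= 66.0):
        raise ValueError("latitude must be within [-66, 66] degrees")
    df = daily.copy()
    if "date" in df.columns:
        df = df.set_index(pd.DatetimeIndex(pd.to_datetime(df["date"])))
    dates = pd.DatetimeIndex(df.index).normalize()
    tmin = df["tmin_c"].to_numpy(dtype=float)
    tmax = df["tmax_c"].to_numpy(dtype=float)
    if np.any(tmin > tmax):
        bad = dates[np.nonzero(tmin > tmax)[0][0]].date()
        raise ValueError(f"tmin exceeds tmax on {bad}")
    if len(dates) > 1 and not np.all(np.diff(dates.asi8) == 86_400_000_000_000):
        raise ValueError("daily records must be consecutive calendar days")

    doy = dates.dayofyear.to_numpy(dtype=float)
    dl = daylength(latitude, doy)
    sunrise = 12.0 - dl / 2.0
    h_min = np.clip(np.rint(sunrise), 1, 11).astype(int)
    h_max = np.clip(np.rint(sunrise + (dl + 4.0) / 2.0), h_min + 1, 23).astype(int)

    n = len(dates)
    # ghost days replicate the boundary days so the first morning and last
    # night have a well-defined decay source/target
    tmin_prev = np.concatenate([[tmin[0]], tmin[:-1]])
    tmax_prev = np.concatenate([[tmax[0]], tmax[:-1]])
    tmin_next = np.concatenate([tmin[1:], [tmin[-1]]])
    h_min_prev = np.concatenate([[h_min[0]], h_min[:-1]])
    h_max_prev = np.concatenate([[h_max[0]], h_max[:-1]])
    h_min_next = np.concatenate([h_min[1:], [h_min[-1]]])

    hours = np.arange(24.0)
    hh = np.broadcast_to(hours, (n, 24))
    hmin = h_min[:, None]
    hmax = h_max[:, None]

    # rising quarter-sine between sunrise and time-of-max
    with np.errstate(invalid="ignore"):
        rise = tmin[:, None] + (tmax - tmin)[:, None] * np.sin(
            0.5 * np.pi * (hh - hmin) / (hmax - hmin)
        )
    # evening decay: from today's max toward tomorrow's min at tomorrow's sunrise
    night_len = (h_min_next + 24 - h_max)[:, None].astype(float)
    evening = tmax[:, None] - (tmax - tmin_next)[:, None] * (
        np.log(hh - hmax + 1.0, where=hh > hmax, out=np.zeros((n, 24)))
        / np.log(night_len + 1.0)
    )
    # morning tail of the previous night's decay, targeting today's min
    night_len_prev = (h_min + 24 - h_max_prev)[:, None].astype(float)
    morning = tmax_prev[:, None] - (tmax_prev - tmin)[:, None] * (
        np.log(hh + 24.0 - h_max_prev[:, None] + 1.0) / np.log(night_len_prev + 1.0)
    )

    values = np.where(
        hh < hmin, morning, np.where(hh <= hmax, rise, evening)
    )

    # per-day affine renormalization: sampled extremes == input extremes
    vmin = values.min(axis=1, keepdims=True)
    vmax = values.max(axis=1, keepdims=True)
    span = vmax - vmin
    flat = span[:, 0] <= 1e-12
    scale = np.where(flat[:, None], 0.0, (tmax - tmin)[:, None] / np.where(flat[:, None], 1.0, span))
    values = tmin[:, None] + (values - vmin) * scale
    values[flat] = ((tmin + tmax) / 2.0)[flat, None]

    index = pd.DatetimeIndex(
        np.repeat(dates.asi8, 24) + np.tile(np.arange(24) * 3_600_000_000_000, n)
    )
    return HourlyTempSeries(
        pd.Series(values.ravel(), index=index, name="temp_c"),
        station_id=station_id,
        latitude=latitude,
    )


# ---------------------------------------------------------------------------
# Semi-hourly resampling
# ---------------------------------------------------------------------------


def resample_semihourly(
    temps: pd.Series,
    max_gap_hours: float = 6.0,
    station_id: str = "station",
    latitude: float = 40.0,
) -> HourlyTempSeries:
    """Hourly means from a 30-minute station record.

    The record is aligned to a regular 30-minute grid; gaps of at most
    ``max_gap_hours`` are filled by linear interpolation, longer gaps raise
    an error naming the span.  Each clock hour becomes the mean of its two
    half-hour readings.
    """
    if not isinstance(temps.index, pd.DatetimeIndex):
        raise TypeError("temps must be indexed by a DatetimeIndex")
    temps = temps.sort_index()
    grid = pd.date_range(temps.index[0].floor("30min"), temps.index[-1], freq="30min")
    aligned = temps.reindex(grid)
    missing = aligned.isna()
    if missing.any():
        runs = (missing != missing.shift()).cumsum()
        for _, run in aligned[missing].groupby(runs[missing]):
            gap_h = len(run) * 0.5
            if gap_h > max_gap_hours:
                raise ValueError(
                    f"gap of {gap_h:.1f} h from {run.index[0]} to {run.index[-1]} "
                    f"exceeds the {max_gap_hours} h limit"
                )
        aligned = aligned.interpolate(method="time", limit_area="inside")
        if aligned.isna().any():
            raise ValueError("record starts or ends with missing readings")
    hourly = aligned.groupby(aligned.index.floor("h")).mean()
    hourly.index = pd.DatetimeIndex(hourly.index)
    return HourlyTempSeries(hourly, station_id=station_id, latitude=latitude)
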