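"""Historic and future winter-temperature scenarios and chill availability.

A *scenario* is a set of 12 monthly means of daily Tmin and Tmax.
Historic scenarios are 15-year running means of a station record centred
on reference years (1980, 1990, …, 2020 by default); future scenarios come
from GCM projection tables (one scenario per GCM × RCP × horizon, 60 by
default).  A single-site stochastic weather generator — a bivariate
(Tmin, Tmax) AR(1) process calibrated on the station record and
conditioned on the scenario's monthly means — produces replicate winters
(100 by default), and chill availability is the Dynamic-model CP total
per replicate over the accumulation window (Oct 1 – Feb 18 by default).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from . import thermal
from .thermal import HourlyTempSeries

__all__ = [
    "MonthlyScenario",
    "ScenarioEnsemble",
    "GeneratorParams",
    "monthly_normals",
    "historic_scenarios",
    "future_scenarios",
    "calibrate_generator",
    "simulate_seasons",
    "chill_availability",
    "DEFAULT_REFERENCE_YEARS",
    "CHILL_WINDOW",
]

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_YEARS = (1980, 1990, 2000, 2010, 2020)
RUNNING_MEAN_YEARS = 15

# chill-availability window within the dormancy season: Oct 1 to Feb 18
# (first flowering date of the earliest cultivar); (month, day) pairs.
CHILL_WINDOW = ((10, 1), (2, 18))

_MID_MONTH_DOY = np.array(
    [15.5, 45.0, 74.5, 105.0, 135.5, 166.0, 196.5, 227.5, 258.0, 288.5, 319.0, 349.5]
)


@dataclasses.dataclass(frozen=True)
class MonthlyScenario:
    """Monthly means of daily temperature extremes defining one scenario."""

    kind: str  # "historic" | "future"
    tmin_means: tuple
    tmax_means: tuple
    reference_year: int | None = None
    gcm: str | None = None
    rcp: str | None = None
    horizon: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("historic", "future"):
            raise ValueError("kind must be 'historic' or 'future'")
        if len(self.tmin_means) != 12 or len(self.tmax_means) != 12:
            raise ValueError("scenario needs 12 monthly means of Tmin and Tmax")
        for m, (lo, hi) in enumerate(zip(self.tmin_means, self.tmax_means), start=1):
            if lo > hi:
                raise ValueError(f"month {m}: mean Tmin {lo} exceeds mean Tmax {hi}")

    @property
    def scenario_id(self) -> str:
        if self.kind == "historic":
            return f"historic-{self.reference_year}"
        return f"{self.gcm}-{self.rcp}-{self.horizon}"

    def shifted(self, delta_c: float) -> "MonthlyScenario":
        """Uniformly warmed (or cooled) copy of this scenario."""
        return dataclasses.replace(
            self,
            tmin_means=tuple(v + delta_c for v in self.tmin_means),
            tmax_means=tuple(v + delta_c for v in self.tmax_means),
        )


@dataclasses.dataclass
class ScenarioEnsemble:
    """Replicate seasonal CP totals (chill availability) for one scenario."""

    scenario: MonthlyScenario | None
    cp_totals: np.ndarray
    seed: int | None = None
    window: tuple = CHILL_WINDOW

    def __post_init__(self) -> None:
        self.cp_totals = np.asarray(self.cp_totals, dtype=float)
        if np.any(self.cp_totals < 0):
            raise ValueError("replicate CP totals must be nonnegative")

    @property
    def n_replicates(self) -> int:
        return len(self.cp_totals)

    @property
    def median_cp(self) -> float:
        return float(np.median(self.cp_totals))

    def quantiles(self, q=(0.25, 0.75)) -> np.ndarray:
        return np.quantile(self.cp_totals, q)


def _daily_table(record: pd.DataFrame) -> pd.DataFrame:
    df = record.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month
    return df


def monthly_normals(record: pd.DataFrame) -> pd.DataFrame:
    """12-row table of mean daily Tmin/Tmax per calendar month."""
    df = _daily_table(record)
    out = (
        df.groupby("month")[["tmin_c", "tmax_c"]]
        .mean()
        .rename(columns={"tmin_c": "tmin_mean_c", "tmax_c": "tmax_mean_c"})
        .reset_index()
    )
    return out


def historic_scenarios(
    record: pd.DataFrame,
    reference_years: Sequence[int] = DEFAULT_REFERENCE_YEARS,
    window_years: int = RUNNING_MEAN_YEARS,
) -> list[MonthlyScenario]:
    """Typical-year scenarios from a running mean of monthly extremes.

    For each reference year and calendar month, the scenario value is the
    mean of that month's mean daily Tmin (and Tmax) over the
    ``window_years``-year window centred on the reference year.  Windows
    extending past the record are truncated with a warning; a reference
    year outside the record raises.
    """
    df = _daily_table(record)
    by_year_month = df.groupby(["year", "month"])[["tmin_c", "tmax_c"]].mean()
    years = df["year"].unique()
    half = window_years // 2
    scenarios = []
    for ref in reference_years:
        if ref < years.min() or ref > years.max():
            raise ValueError(
                f"reference year {ref} outside record ({years.min()}–{years.max()})"
            )
        lo, hi = ref - half, ref + half
        if lo < years.min() or hi > years.max():
            warnings.warn(
                f"running-mean window {lo}–{hi} for {ref} truncated to the record",
                stacklevel=2,
            )
        in_window = by_year_month.loc[
            (by_year_month.index.get_level_values("year") >= lo)
            & (by_year_month.index.get_level_values("year") <= hi)
        ]
        means = in_window.groupby("month").mean()
        if list(means.index) != list(range(1, 13)):
            raise ValueError(f"record lacks full monthly coverage around {ref}")
        scenarios.append(
            MonthlyScenario(
                kind="historic",
                reference_year=int(ref),
                tmin_means=tuple(means["tmin_c"]),
                tmax_means=tuple(means["tmax_c"]),
            )
        )
    return scenarios


def future_scenarios(gcm_table: pd.DataFrame) -> list[MonthlyScenario]:
    """One scenario per (GCM, RCP, horizon) from a projection table.

    The table needs columns ``gcm``, ``rcp``, ``horizon``, ``month``,
    ``tmin_mean_c``, ``tmax_mean_c`` with all 12 months per combination
    (missing months raise, listing them).  Values are carried through
    unchanged.
    """
    required = {"gcm", "rcp", "horizon", "month", "tmin_mean_c", "tmax_mean_c"}
    missing_cols = required - set(gcm_table.columns)
    if missing_cols:
        raise ValueError(f"GCM table missing columns: {sorted(missing_cols)}")
    scenarios = []
    for (gcm, rcp, horizon), group in gcm_table.groupby(["gcm", "rcp", "horizon"]):
        months = sorted(group["month"].tolist())
        if months != list(range(1, 13)):
            lacking = sorted(set(range(1, 13)) - set(months))
            raise ValueError(
                f"{gcm}/{rcp}/{horizon}: missing months {lacking}"
            )
        g = group.sort_values("month")
        scenarios.append(
            MonthlyScenario(
                kind="future",
                gcm=str(gcm),
                rcp=str(rcp),
                horizon=int(horizon),
                tmin_means=tuple(g["tmin_mean_c"]),
                tmax_means=tuple(g["tmax_mean_c"]),
            )
        )
    return scenarios


# ---------------------------------------------------------------------------
# Weather generator
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GeneratorParams:
    """Per-calendar-month residual statistics of a station record.

    Arrays of length 12: anomaly standard deviations of daily Tmin and
    Tmax about the smooth seasonal cycle, the Tmin–Tmax anomaly
    correlation, and the lag-1 autocorrelations.
    """

    sd_tmin: np.ndarray
    sd_tmax: np.ndarray
    corr_minmax: np.ndarray
    rho_tmin: np.ndarray
    rho_tmax: np.ndarray

    def __post_init__(self) -> None:
        for name in ("sd_tmin", "sd_tmax", "corr_minmax", "rho_tmin", "rho_tmax"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have 12 monthly values")
            setattr(self, name, arr)


def _periodic_daily_curve(monthly_values: np.ndarray, day_of_year: np.ndarray) -> np.ndarray:
    """Smooth periodic interpolation of 12 mid-month anchors to days."""
    x = np.concatenate([_MID_MONTH_DOY, [_MID_MONTH_DOY[0] + 365.0]])
    y = np.concatenate([monthly_values, [monthly_values[0]]])
    spline = CubicSpline(x, y, bc_type="periodic")
    doy = np.mod(np.asarray(day_of_year, dtype=float) - x[0], 365.0) + x[0]
    return spline(doy)


def calibrate_generator(record: pd.DataFrame, min_years: int = 5) -> GeneratorParams:
    """Estimate the weather-generator parameters from a daily record.

    Anomalies are daily extremes minus the smooth seasonal cycle obtained
    by periodic interpolation of the record's monthly normals; statistics
    are then computed per calendar month (lag-1 autocorrelation uses
    consecutive-day pairs whose first day falls in the month).
    """
    df = _daily_table(record)
    n_years = df["year"].nunique()
    if n_years < min_years:
        raise ValueError(f"need >= {min_years} years of daily data, got {n_years}")
    normals = monthly_normals(record)
    doy = df["date"].dt.dayofyear.to_numpy(dtype=float)
    anom_min = df["tmin_c"].to_numpy() - _periodic_daily_curve(
        normals["tmin_mean_c"].to_numpy(), doy
    )
    anom_max = df["tmax_c"].to_numpy() - _periodic_daily_curve(
        normals["tmax_mean_c"].to_numpy(), doy
    )
    month = df["month"].to_numpy()
    consecutive = np.diff(df["date"].to_numpy()).astype("timedelta64[D]") == np.timedelta64(1, "D")

    sd_tmin = np.empty(12)
    sd_tmax = np.empty(12)
    corr = np.empty(12)
    rho_min = np.empty(12)
    rho_max = np.empty(12)
    for m in range(1, 13):
        sel = month == m
        if sel.sum() < 10:
            raise ValueError(f"insufficient data in month {m}")
        a, b = anom_min[sel], anom_max[sel]
        sd_tmin[m - 1] = a.std(ddof=1)
        sd_tmax[m - 1] = b.std(ddof=1)
        if sd_tmin[m - 1] > 0 and sd_tmax[m - 1] > 0:
            corr[m - 1] = np.corrcoef(a, b)[0, 1]
        else:
            corr[m - 1] = 0.0
        lag = sel[:-1] & consecutive
        rho_min[m - 1] = _lag1(anom_min, lag)
        rho_max[m - 1] = _lag1(anom_max, lag)
    return GeneratorParams(
        sd_tmin=sd_tmin,
        sd_tmax=sd_tmax,
        corr_minmax=corr,
        rho_tmin=rho_min,
        rho_tmax=rho_max,
    )


def _lag1(anom: np.ndarray, first_day_mask: np.ndarray) -> float:
    x = anom[:-1][first_day_mask]
    y = anom[1:][first_day_mask]
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def simulate_seasons(
    scenario: MonthlyScenario,
    params: GeneratorParams,
    n_replicates: int = 100,
    seed: int = 0,
    season_start: tuple = (10, 1),
    season_end: tuple = (2, 28),
    base_year: int = 2000,
) -> pd.DataFrame:
    """Replicate winter seasons of daily extremes for one scenario.

    Daily target means come from a periodic smooth curve through the
    scenario's mid-month anchors; bivariate AR(1) anomalies with the
    calibrated per-month sd, Tmin–Tmax correlation and lag-1
    autocorrelation are added.  Tmin ≤ Tmax is enforced by swapping (the
    count of swaps is logged).  Returns a long table with columns
    ``replicate``, ``date``, ``tmin_c``, ``tmax_c``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    start = _dt.date(base_year, *season_start)
    end = _dt.date(base_year + 1, *season_end)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    target_min = _periodic_daily_curve(np.asarray(scenario.tmin_means), doy)
    target_max = _periodic_daily_curve(np.asarray(scenario.tmax_means), doy)
    month_idx = dates.month.to_numpy() - 1

    rng = np.random.default_rng(seed)
    n_days = len(dates)
    sd_min = params.sd_tmin[month_idx]
    sd_max = params.sd_tmax[month_idx]
    corr = np.clip(params.corr_minmax[month_idx], -0.999, 0.999)
    rho_min = np.clip(params.rho_tmin[month_idx], -0.999, 0.999)
    rho_max = np.clip(params.rho_tmax[month_idx], -0.999, 0.999)

    # standardized bivariate AR(1): z_t = rho z_{t-1} + sqrt(1-rho^2) eps_t,
    # eps correlated across the two variables
    z_min = np.zeros((n_replicates, n_days))
    z_max = np.zeros((n_replicates, n_days))
    e1 = rng.standard_normal((n_replicates, n_days))
    e2 = rng.standard_normal((n_replicates, n_days))
    for t in range(n_days):
        c = corr[t]
        eps_min = e1[:, t]
        eps_max = c * e1[:, t] + np.sqrt(1.0 - c * c) * e2[:, t]
        if t == 0:
            z_min[:, 0] = eps_min
            z_max[:, 0] = eps_max
        else:
            z_min[:, t] = rho_min[t] * z_min[:, t - 1] + np.sqrt(1 - rho_min[t] ** 2) * eps_min
            z_max[:, t] = rho_max[t] * z_max[:, t - 1] + np.sqrt(1 - rho_max[t] ** 2) * eps_max
    tmin = target_min[None, :] + sd_min[None, :] * z_min
    tmax = target_max[None, :] + sd_max[None, :] * z_max
    swapped = tmin > tmax
    if swapped.any():
        logger.info(
            "simulate_seasons(%s): swapped Tmin/Tmax on %d of %d replicate-days",
            scenario.scenario_id,
            int(swapped.sum()),
            tmin.size,
        )
        lo = np.minimum(tmin, tmax)
        hi = np.maximum(tmin, tmax)
        tmin, tmax = lo, hi
    frames = pd.DataFrame(
        {
            "replicate": np.repeat(np.arange(n_replicates), n_days),
            "date": np.tile(dates.to_numpy(), n_replicates),
            "tmin_c": tmin.ravel(),
            "tmax_c": tmax.ravel(),
        }
    )
    return frames


def chill_availability(
    replicates: pd.DataFrame,
    latitude: float,
    scenario: MonthlyScenario | None = None,
    window: tuple = CHILL_WINDOW,
    seed: int | None = None,
) -> ScenarioEnsemble:
    """Dynamic-model CP total per replicate winter over the chill window.

    ``replicates`` is the long table produced by :func:`simulate_seasons`.
    Each replicate's daily extremes are expanded to hourly temperatures
    and run through the Dynamic model from the window start (Oct 1) to the
    window end (Feb 18 by default), inclusive.
    """
    df = replicates.copy()
    df["date"] = pd.to_datetime(df["date"])
    (m0, d0), (m1, d1) = window
    temps_rows = []
    labels = []
    for rep, group in df.groupby("replicate"):
        g = group.sort_values("date")
        year0 = g["date"].iloc[0].year
        start = pd.Timestamp(year0, m0, d0)
        end = pd.Timestamp(year0 + 1 if (m1, d1) < (m0, d0) else year0, m1, d1)
        series = thermal.hourly_from_daily(
            g[["date", "tmin_c", "tmax_c"]], latitude, station_id=f"replicate-{rep}"
        )
        temps_rows.append(series.window(start.date(), end.date()).to_numpy())
        labels.append(rep)
    lengths = {len(t) for t in temps_rows}
    if len(lengths) != 1:
        raise ValueError("replicates cover unequal chill windows")
    temps = np.vstack(temps_rows)
    hourly, _ = thermal.dynamic_portions(temps)
    cp_totals = hourly.sum(axis=1)
    return ScenarioEnsemble(
        scenario=scenario, cp_totals=cp_totals, seed=seed, window=window
    )
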