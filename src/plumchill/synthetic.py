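"""Synthetic inputs for the dormancy-agroclimatics pipeline.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes: Mediterranean-type station
records with a sinusoidal annual cycle and AR(1) daily anomalies,
forcing-experiment bud-weight series with a step increase at a known
endodormancy-release date, logistic bloom curves, and pseudo-GCM
projection tables with additive warming deltas.

Two climate presets bracket the study system: ``BADAJOZ_LIKE`` (a mild
south-western Mediterranean winter) and ``ZARAGOZA_LIKE`` (a colder
semi-arid inland winter).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .thermal import HourlyTempSeries, hourly_from_daily

__all__ = [
    "SyntheticClimateSpec",
    "SyntheticForcingSpec",
    "generate_station_record",
    "generate_forcing_experiment",
    "generate_bloom_curve",
    "generate_gcm_table",
    "BADAJOZ_LIKE",
    "ZARAGOZA_LIKE",
    "DEFAULT_RCP_DELTAS",
]

# day-of-year of the coldest day of the annual cycle (mid-January)
_COLDEST_DOY = 15.0
_YEAR_DAYS = 365.25


@dataclasses.dataclass(frozen=True)
class SyntheticClimateSpec:
    """Parameters of a synthetic single-station climate.

    The daily-mean cycle is ``annual_mean − amplitude·cos(2π(doy−15)/365.25)``
    (coldest mid-January); Tmin/Tmax sit half the diurnal range below/above
    it.  A shared AR(1) anomaly (perfectly correlated between Tmin and Tmax)
    plus small independent jitter is added per day.
    """

    annual_mean_c: float = 16.0
    seasonal_amplitude_c: float = 8.0
    diurnal_range_c: float = 10.0
    anomaly_autocorr: float = 0.7
    anomaly_sd_c: float = 2.0
    latitude: float = 40.0
    warming_trend_c_per_decade: float = 0.0
    jitter_sd_c: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seasonal_amplitude_c < 0:
            raise ValueError("seasonal_amplitude_c must be >= 0")
        if self.diurnal_range_c < 0:
            raise ValueError("diurnal_range_c must be >= 0")
        if not abs(self.anomaly_autocorr) < 1:
            raise ValueError("anomaly_autocorr must satisfy |rho| < 1")
        if self.anomaly_sd_c < 0:
            raise ValueError("anomaly_sd_c must be >= 0")
        if self.jitter_sd_c < 0:
            raise ValueError("jitter_sd_c must be >= 0")
        if not -66.0 <= self.latitude <= 66.0:
            raise ValueError("latitude must be within [-66, 66]")


BADAJOZ_LIKE = SyntheticClimateSpec(
    annual_mean_c=16.8,
    seasonal_amplitude_c=7.8,
    diurnal_range_c=10.5,
    anomaly_autocorr=0.7,
    anomaly_sd_c=2.0,
    latitude=38.85,
    seed=38,
)
"""Mild Mediterranean preset (January means ≈ 4/14.5 °C)."""

ZARAGOZA_LIKE = SyntheticClimateSpec(
    annual_mean_c=15.0,
    seasonal_amplitude_c=9.0,
    diurnal_range_c=10.0,
    anomaly_autocorr=0.7,
    anomaly_sd_c=2.2,
    latitude=41.7,
    seed=41,
)
"""Colder semi-arid preset (January means ≈ 1/11 °C)."""

DEFAULT_RCP_DELTAS: Mapping[str, Mapping[int, float]] = {
    "RCP4.5": {2050: 1.4, 2085: 1.9},
    "RCP8.5": {2050: 2.0, 2085: 4.3},
}
"""Mean warming (°C) over the late-20th-century baseline per RCP × horizon."""


def seasonal_mean(spec: SyntheticClimateSpec, day_of_year) -> np.ndarray:
    """Daily-mean temperature of the deterministic annual cycle."""
    doy = np.asarray(day_of_year, dtype=float)
    return spec.annual_mean_c - spec.seasonal_amplitude_c * np.cos(
        2.0 * np.pi * (doy - _COLDEST_DOY) / _YEAR_DAYS
    )


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path with marginal standard deviation ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * math.sqrt(1.0 - rho * rho)
    eps = rng.normal(0.0, innov_sd, size=n)
    path = np.empty(n)
    path[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        path[i] = rho * path[i - 1] + eps[i]
    return path


def generate_station_record(
    spec: SyntheticClimateSpec,
    start_year: int,
    n_years: int,
    station_id: str | None = None,
) -> tuple[pd.DataFrame, HourlyTempSeries]:
    """Generate a multi-year station record.

    Returns the daily-extremes table (columns ``date``, ``tmin_c``,
    ``tmax_c``) and the hourly series derived from it via the idealized
    day-curve.  Output is reproducible given ``spec.seed``.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(spec.seed)
    dates = pd.date_range(
        f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D"
    )
    doy = dates.dayofyear.to_numpy(dtype=float)
    years_elapsed = (dates - dates[0]).days.to_numpy() / _YEAR_DAYS
    mean = seasonal_mean(spec, doy) + spec.warming_trend_c_per_decade * years_elapsed / 10.0
    anom = _ar1(rng, len(dates), spec.anomaly_autocorr, spec.anomaly_sd_c)
    jitter_min = rng.normal(0.0, spec.jitter_sd_c, len(dates)) if spec.jitter_sd_c else np.zeros(len(dates))
    jitter_max = rng.normal(0.0, spec.jitter_sd_c, len(dates)) if spec.jitter_sd_c else np.zeros(len(dates))
    half = spec.diurnal_range_c / 2.0
    tmin = mean - half + anom + jitter_min
    tmax = mean + half + anom + jitter_max
    # realism bound: Tmin <= Tmax always (swap the rare jitter-driven inversions)
    lo = np.minimum(tmin, tmax)
    hi = np.maximum(tmin, tmax)
    daily = pd.DataFrame({"date": dates, "tmin_c": lo, "tmax_c": hi})
    sid = station_id or f"synthetic-{spec.seed}"
    hourly = hourly_from_daily(daily, spec.latitude, station_id=sid)
    return daily, hourly


# ---------------------------------------------------------------------------
# Forcing experiments
# ---------------------------------------------------------------------------

RELEASE_THRESHOLD = 0.30


@dataclasses.dataclass(frozen=True)
class SyntheticForcingSpec:
    """Parameters of a synthetic forcing experiment.

    Buds sampled before ``release_date`` gain ``prerelease_multiplier − 1``
    weight over the 8-day forcing period; on/after it they gain
    ``released_multiplier − 1`` (which must exceed the 30 % detection
    threshold).  Per-bud lognormal-ish noise is applied independently to
    the day-0 and day-8 weights.
    """

    release_date: _dt.date = _dt.date(2020, 1, 2)
    baseline_weight_g: float = 0.02
    released_multiplier: float = 2.0
    prerelease_multiplier: float = 1.05
    noise_sd_g: float = 0.002
    sampling_interval_days: int = 7
    n_buds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.released_multiplier <= 1.0 + RELEASE_THRESHOLD:
            raise ValueError(
                "released_multiplier must exceed 1 + release threshold "
                f"({1.0 + RELEASE_THRESHOLD})"
            )
        if self.sampling_interval_days < 1:
            raise ValueError("sampling_interval_days must be >= 1 day")
        if self.baseline_weight_g <= 0:
            raise ValueError("baseline_weight_g must be positive")
        if self.noise_sd_g < 0:
            raise ValueError("noise_sd_g must be >= 0")
        if self.n_buds < 1:
            raise ValueError("n_buds must be >= 1")


def generate_forcing_experiment(
    spec: SyntheticForcingSpec,
    season_start: _dt.date,
    season_end: _dt.date,
    cultivar: str = "synthetic",
    location: str = "synthetic",
) -> pd.DataFrame:
    """Weekly bud-weight records for one cultivar-season.

    Returns the forcing table (cultivar, location, season, sampling_date,
    bud_id, weight_day0_g, weight_day8_g), one row per weighed bud.
    The season label is the starting calendar year of the window.
    """
    season_start = pd.Timestamp(season_start)
    season_end = pd.Timestamp(season_end)
    release = pd.Timestamp(spec.release_date)
    if not season_start <= release <= season_end:
        raise ValueError(
            f"release date {release.date()} outside sampling window "
            f"{season_start.date()}–{season_end.date()}"
        )
    rng = np.random.default_rng(spec.seed)
    dates = pd.date_range(season_start, season_end, freq=f"{spec.sampling_interval_days}D")
    season = season_start.year if season_start.month >= 7 else season_start.year - 1
    rows = []
    floor = 1e-4  # weights must stay positive
    for date in dates:
        mult = spec.released_multiplier if date >= release else spec.prerelease_multiplier
        w0 = np.maximum(
            spec.baseline_weight_g + rng.normal(0.0, spec.noise_sd_g, spec.n_buds), floor
        )
        w8 = np.maximum(w0 * mult + rng.normal(0.0, spec.noise_sd_g, spec.n_buds), floor)
        for bud, (a, b) in enumerate(zip(w0, w8)):
            rows.append(
                {
                    "cultivar": cultivar,
                    "location": location,
                    "season": season,
                    "sampling_date": date,
                    "bud_id": bud,
                    "weight_day0_g": a,
                    "weight_day8_g": b,
                }
            )
    return pd.DataFrame(rows)


def generate_bloom_curve(
    f50_date: _dt.date,
    scale_days: float = 3.0,
    observation_interval_days: int = 2,
    n_obs: int = 15,
    cultivar: str = "synthetic",
    location: str = "synthetic",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Logistic flowering-progress records around a bloom midpoint.

    The fraction of open flowers follows ``1/(1+exp(−(t−t50)/scale))``
    observed every ``observation_interval_days`` days, optionally with
    truncated Gaussian observation noise.
    """
    mid = pd.Timestamp(f50_date)
    offsets = (np.arange(n_obs) - n_obs // 2) * observation_interval_days
    dates = mid + pd.to_timedelta(offsets, unit="D")
    t = offsets.astype(float)
    frac = 1.0 / (1.0 + np.exp(-t / scale_days))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frac = np.clip(frac + rng.normal(0.0, noise_sd, len(frac)), 0.0, 1.0)
    return pd.DataFrame(
        {
            "cultivar": cultivar,
            "location": location,
            "date": dates,
            "fraction_open": frac,
        }
    )


# ---------------------------------------------------------------------------
# Pseudo-GCM projection tables
# ---------------------------------------------------------------------------


def generate_gcm_table(
    baseline_monthly: pd.DataFrame,
    n_gcms: int = 15,
    rcp_deltas: Mapping[str, Mapping[int, float]] = DEFAULT_RCP_DELTAS,
    gcm_spread_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Monthly Tmin/Tmax projections for an ensemble of pseudo-GCMs.

    ``baseline_monthly`` needs columns ``month``, ``tmin_mean_c``,
    ``tmax_mean_c`` (12 rows).  Each (GCM, RCP, horizon, month) row is the
    baseline plus the RCP/horizon warming delta plus a per-GCM systematic
    offset drawn once (sd ``gcm_spread_sd``) and reused across months,
    RCPs and horizons — mimicking between-model bias in a real ensemble.
    """
    required = {"month", "tmin_mean_c", "tmax_mean_c"}
    if baseline_monthly is None or len(baseline_monthly) == 0:
        raise ValueError("baseline_monthly must be a non-empty 12-month table")
    missing = required - set(baseline_monthly.columns)
    if missing:
        raise ValueError(f"baseline_monthly missing columns: {sorted(missing)}")
    base = baseline_monthly.sort_values("month").reset_index(drop=True)
    if list(base["month"]) != list(range(1, 13)):
        raise ValueError("baseline_monthly must contain months 1..12 exactly once")
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, gcm_spread_sd, n_gcms) if gcm_spread_sd > 0 else np.zeros(n_gcms)
    rows = []
    for g in range(n_gcms):
        gcm = f"GCM{g + 1:02d}"
        for rcp, horizons in rcp_deltas.items():
            for horizon, delta in horizons.items():
                shift = delta + offsets[g]
                for _, row in base.iterrows():
                    rows.append(
                        {
                            "gcm": gcm,
                            "rcp": rcp,
                            "horizon": int(horizon),
                            "month": int(row["month"]),
                            "tmin_mean_c": row["tmin_mean_c"] + shift,
                            "tmax_mean_c": row["tmax_mean_c"] + shift,
                        }
                    )
    return pd.DataFrame(rows)
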