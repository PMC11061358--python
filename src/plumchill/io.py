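"""CSV readers/writers and pipeline configuration.

All tables travel as UTF-8 CSV with exact header names.  Readers validate
required columns (missing ones raise), warn about unknown columns, and
report malformed dates with their row number.  Writers round-trip floats
exactly (shortest-repr formatting).

Schemas
-------
station hourly     timestamp, temp_c            (also accepts 30-min cadence)
daily extremes     date, tmin_c, tmax_c
forcing            cultivar, location, season, sampling_date, bud_id,
                   weight_day0_g, weight_day8_g
phenology          cultivar, location, date, fraction_open
GCM table          gcm, rcp, horizon, month, tmin_mean_c, tmax_mean_c
requirements out   cultivar, location, season, er_date, f50_date,
                   cr_ch, cr_cu, cr_cp, hr_gdh
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .thermal import HourlyTempSeries, resample_semihourly

__all__ = [
    "PipelineConfig",
    "read_station_csv",
    "read_daily_csv",
    "write_daily_csv",
    "read_forcing_csv",
    "write_forcing_csv",
    "read_phenology_csv",
    "write_phenology_csv",
    "read_gcm_csv",
    "write_gcm_csv",
    "write_requirements_csv",
    "read_requirements_csv",
]

_SCHEMAS = {
    "station": ("timestamp", "temp_c"),
    "daily": ("date", "tmin_c", "tmax_c"),
    "forcing": (
        "cultivar",
        "location",
        "season",
        "sampling_date",
        "bud_id",
        "weight_day0_g",
        "weight_day8_g",
    ),
    "phenology": ("cultivar", "location", "date", "fraction_open"),
    "gcm": ("gcm", "rcp", "horizon", "month", "tmin_mean_c", "tmax_mean_c"),
    "requirements": (
        "cultivar",
        "location",
        "season",
        "er_date",
        "f50_date",
        "cr_ch",
        "cr_cu",
        "cr_cp",
        "hr_gdh",
    ),
}


def _read_csv(path, schema: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, encoding="utf-8")
    required = _SCHEMAS[schema]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    unknown = set(df.columns) - set(required)
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {sorted(unknown)}", stacklevel=3)
    return df[list(required)]


def _parse_dates(df: pd.DataFrame, column: str, path) -> pd.DataFrame:
    parsed = pd.to_datetime(df[column], format="ISO8601", errors="coerce")
    bad = parsed.isna() & df[column].notna()
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValueError(
            f"{path}: malformed date {df[column].iloc[row]!r} in column "
            f"{column!r} at data row {row + 1}"
        )
    df = df.copy()
    df[column] = parsed
    return df


def read_station_csv(path, station_id: str | None = None, latitude: float = 40.0) -> HourlyTempSeries:
    """Read an hourly (or semi-hourly) station record.

    Semi-hourly cadence is detected from the median timestamp spacing and
    resampled to hourly means with short-gap interpolation.
    """
    df = _read_csv(path, "station")
    df = _parse_dates(df, "timestamp", path)
    series = pd.Series(
        df["temp_c"].to_numpy(dtype=float),
        index=pd.DatetimeIndex(df["timestamp"]),
        name="temp_c",
    ).sort_index()
    sid = station_id or Path(path).stem
    spacing = series.index.to_series().diff().median()
    if spacing == pd.Timedelta(minutes=30):
        return resample_semihourly(series, station_id=sid, latitude=latitude)
    return HourlyTempSeries(series, station_id=sid, latitude=latitude)


def read_daily_csv(path) -> pd.DataFrame:
    df = _read_csv(path, "daily")
    return _parse_dates(df, "date", path)


def write_daily_csv(df: pd.DataFrame, path) -> None:
    out = df[list(_SCHEMAS["daily"])].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, encoding="utf-8")


def read_forcing_csv(path) -> pd.DataFrame:
    df = _read_csv(path, "forcing")
    return _parse_dates(df, "sampling_date", path)


def write_forcing_csv(df: pd.DataFrame, path) -> None:
    out = df[list(_SCHEMAS["forcing"])].copy()
    out["sampling_date"] = pd.to_datetime(out["sampling_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, encoding="utf-8")


def read_phenology_csv(path) -> pd.DataFrame:
    df = _read_csv(path, "phenology")
    return _parse_dates(df, "date", path)


def write_phenology_csv(df: pd.DataFrame, path) -> None:
    out = df[list(_SCHEMAS["phenology"])].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, encoding="utf-8")


def read_gcm_csv(path) -> pd.DataFrame:
    return _read_csv(path, "gcm")


def write_gcm_csv(df: pd.DataFrame, path) -> None:
    df[list(_SCHEMAS["gcm"])].to_csv(path, index=False, encoding="utf-8")


def write_requirements_csv(df: pd.DataFrame, path) -> None:
    out = df[list(_SCHEMAS["requirements"])].copy()
    for col in ("er_date", "f50_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, encoding="utf-8")


def read_requirements_csv(path) -> pd.DataFrame:
    df = _read_csv(path, "requirements")
    for col in ("er_date", "f50_date"):
        df = _parse_dates(df, col, path)
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Regions map region names to climate-preset names ("badajoz_like" /
    "zaragoza_like") or inline spec dictionaries; cultivars map cultivar
    names to dormancy-season release-day offsets (days after Oct 1).  All
    stochastic stages derive their streams from ``seed``.
    """

    output_dir: str = "plumchill-output"
    seed: int = 0
    regions: Mapping[str, object] = dataclasses.field(
        default_factory=lambda: {"badajoz": "badajoz_like", "zaragoza": "zaragoza_like"}
    )
    cultivars: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {
            "early-release": 75,
            "mid-release": 85,
            "late-release": 105,
        }
    )
    start_year: int = 1981
    n_years: int = 40
    n_seasons: int = 3
    reference_years: Sequence[int] = (1990, 2000, 2010)
    n_gcms: int = 15
    rcp_deltas: Mapping[str, Mapping[int, float]] | None = None
    gcm_spread_sd: float = 0.5
    n_replicates: int = 100
    n_draws: int = 1000
    chill_window_end: Sequence[int] = (2, 18)
    forcing_noise_sd_g: float = 0.002
    station_files: Mapping[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_years < 1 or self.n_seasons < 1:
            raise ValueError("n_years and n_seasons must be >= 1")
        if self.n_replicates < 1 or self.n_draws < 1:
            raise ValueError("n_replicates and n_draws must be >= 1")
        m, d = self.chill_window_end
        _dt.date(2001, int(m), int(d))  # validates the month/day pair

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
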