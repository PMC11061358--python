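"""Thermal-time model unit, oracle and property tests."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plumchill import thermal
from plumchill.thermal import (
    DynamicModelConstants,
    DynamicModelState,
    HourlyTempSeries,
    accumulate,
    chilling_hours_hour,
    daylength,
    dynamic_model_step,
    dynamic_portions,
    gdh_hour,
    hourly_from_daily,
    resample_semihourly,
    utah_units_hour,
)

# ---------------------------------------------------------------------------
# Per-hour model definitions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "func,temp,expected",
    [
        (chilling_hours_hour, 5.0, 1.0),
        (chilling_hours_hour, -3.0, 0.0),
        (chilling_hours_hour, 7.2, 1.0),  # closed upper boundary
        (chilling_hours_hour, 0.0, 1.0),  # closed lower boundary
        (chilling_hours_hour, 7.3, 0.0),
        (utah_units_hour, 5.0, 1.0),
        (utah_units_hour, 2.0, 0.5),
        (utah_units_hour, 14.0, 0.0),
        (utah_units_hour, 1.0, 0.0),
        (utah_units_hour, 10.0, 0.5),
        (utah_units_hour, 16.0, -0.5),
        (utah_units_hour, 18.0, -1.0),
        (utah_units_hour, 25.0, -1.0),
        (gdh_hour, 30.0, 20.5),  # capped at the 25 degC optimum
        (gdh_hour, 4.5, 0.0),  # base temperature
        (gdh_hour, 10.0, 5.5),
        (gdh_hour, 5.5, 1.0),  # one degree above base
        (gdh_hour, -5.0, 0.0),
    ],
)
def test_hourly_contribution_definitions(func, temp, expected):
    assert func(temp) == pytest.approx(expected)


@pytest.mark.parametrize("func", [chilling_hours_hour, utah_units_hour, gdh_hour])
@pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
def test_hourly_contributions_reject_nonfinite(func, bad):
    with pytest.raises(ValueError):
        func(bad)


def test_vectorized_lookups_match_scalar():
    temps = np.linspace(-10.0, 35.0, 901)  # includes every band boundary
    assert np.array_equal(thermal.chilling_hours(temps), [chilling_hours_hour(t) for t in temps])
    assert np.array_equal(thermal.utah_units(temps), [utah_units_hour(t) for t in temps])
    assert np.allclose(thermal.gdh(temps), [gdh_hour(t) for t in temps])


# ---------------------------------------------------------------------------
# Dynamic model
# ---------------------------------------------------------------------------


def oracle_dynamic_cp(temps, c=DynamicModelConstants()):
    """Straight-line transcription of the two-step kinetic recursion.

    Written independently of the vectorized implementation: plain floats,
    one hour at a time.
    """
    x = 0.0
    portions = 0.0
    per_hour = []
    for t in temps:
        tk = t + 273.0
        sr = math.exp(c.slope * c.transition_k * (tk - c.transition_k) / tk)
        xi = sr / (1.0 + sr)
        xs = c.a0 / c.a1 * math.exp(-(c.e0 - c.e1) / tk)
        ak1 = c.a1 * math.exp(-c.e1 / tk)
        x = xs - (xs - x) * math.exp(-ak1)
        if x >= 1.0:
            delta = xi * x
            x -= delta
        else:
            delta = 0.0
        portions += delta
        per_hour.append(delta)
    return portions, per_hour


# frozen from the oracle above: 720 h at a constant 6 degC
CP_6C_720H = 24.432564407895057


def test_dynamic_constant_6c_matches_oracle_and_frozen_value():
    temps = np.full(720, 6.0)
    expected, _ = oracle_dynamic_cp(temps)
    hourly, _ = dynamic_portions(temps)
    assert hourly.sum() == pytest.approx(expected, abs=1e-9)
    assert hourly.sum() == pytest.approx(CP_6C_720H, abs=1e-9)


def test_dynamic_random_series_matches_oracle():
    rng = np.random.default_rng(42)
    temps = rng.uniform(-5.0, 30.0, 2000)
    expected, per_hour = oracle_dynamic_cp(temps)
    hourly, _ = dynamic_portions(temps)
    assert np.allclose(hourly, per_hour, atol=1e-12)
    assert hourly.sum() == pytest.approx(expected, abs=1e-9)


def test_dynamic_hot_temperature_accumulates_nothing():
    hourly, final_x = dynamic_portions(np.full(96, 30.0))
    assert hourly.sum() == 0.0
    assert final_x < 1.0


def test_dynamic_stepwise_irreversibility_and_state():
    state = DynamicModelState()
    rng = np.random.default_rng(3)
    for temp in rng.uniform(-5.0, 30.0, 200):
        new = dynamic_model_step(state, temp)
        assert new.portions >= state.portions
        assert new.x >= 0.0
        state = new
    # scalar stepping equals the vectorized recursion
    temps = rng.uniform(-5.0, 25.0, 300)
    s = DynamicModelState()
    for t in temps:
        s = dynamic_model_step(s, t)
    hourly, final_x = dynamic_portions(temps)
    assert s.portions == pytest.approx(hourly.sum(), abs=1e-12)
    assert s.x == pytest.approx(final_x, abs=1e-12)


def test_dynamic_2d_vectorization_matches_per_row():
    rng = np.random.default_rng(11)
    temps = rng.uniform(-2.0, 20.0, size=(5, 400))
    hourly2d, x2d = dynamic_portions(temps)
    for i in range(5):
        hourly, x = dynamic_portions(temps[i])
        assert np.allclose(hourly2d[i], hourly)
        assert x2d[i] == pytest.approx(x)


def test_dynamic_rate_constant_at_fixed_temperature():
    """At constant temperature the portions-per-hour rate stabilizes."""
    hourly, _ = dynamic_portions(np.full(3000, 6.0))
    # skip the spin-up before the first conversion event
    first = hourly[1000:2000].sum()
    second = hourly[2000:3000].sum()
    assert second > 0
    assert second == pytest.approx(first, rel=0.01)
    hot, _ = dynamic_portions(np.full(2000, 30.0))
    assert hot.sum() == 0.0


# ---------------------------------------------------------------------------
# accumulate
# ---------------------------------------------------------------------------


def test_accumulate_constant_5c_totals(constant_series):
    series = constant_series(5.0, 24)
    profile = accumulate(series, dt.date(2019, 10, 1), dt.date(2019, 10, 1))
    assert profile.totals["CH"] == 24.0
    assert profile.totals["CU"] == 24.0
    assert profile.totals["GDH"] == pytest.approx(12.0)


def test_accumulate_empty_window(constant_series):
    series = constant_series(5.0, 48)
    profile = accumulate(series, dt.date(2019, 10, 2), dt.date(2019, 10, 1))
    assert all(v == 0.0 for v in profile.totals.values())


def test_accumulate_random_series_matches_bruteforce(winter_series):
    start, end = dt.date(2019, 10, 1), dt.date(2019, 11, 12)  # ~1000 h
    profile = accumulate(winter_series, start, end)
    temps = winter_series.window(start, end).to_numpy()
    assert len(temps) == 43 * 24
    assert profile.totals["CH"] == sum(chilling_hours_hour(t) for t in temps)
    assert profile.totals["CU"] == pytest.approx(sum(utah_units_hour(t) for t in temps))
    assert profile.totals["GDH"] == pytest.approx(sum(gdh_hour(t) for t in temps))


def test_accumulate_window_not_covered_lists_span(constant_series):
    series = constant_series(5.0, 48)
    with pytest.raises(ValueError, match="not covered"):
        accumulate(series, dt.date(2019, 9, 1), dt.date(2019, 10, 1))


def test_cumulative_monotonicity(winter_series):
    profile = accumulate(winter_series, dt.date(2019, 10, 1), dt.date(2020, 2, 18))
    for model in ("CH", "CP", "GDH"):
        assert (np.diff(profile.frame[f"{model}_cum"]) >= -1e-12).all()
    # CU can decrease, but only at hours with temp >= 16 degC
    cu_drops = np.diff(profile.frame["CU_cum"]) < 0
    temps = winter_series.window(dt.date(2019, 10, 1), dt.date(2020, 2, 18)).to_numpy()
    assert np.all(temps[1:][cu_drops] >= 16.0)


def test_accumulate_additivity_and_cp_state_carry(winter_series):
    start, mid, end = dt.date(2019, 10, 1), dt.date(2019, 12, 1), dt.date(2020, 2, 18)
    whole = accumulate(winter_series, start, end)
    first = accumulate(winter_series, start, mid)
    second = accumulate(
        winter_series, mid + dt.timedelta(days=1), end, initial_state=first.final_state
    )
    for model in ("CH", "CU", "GDH"):
        assert first.totals[model] + second.totals[model] == pytest.approx(
            whole.totals[model]
        )
    # CP additivity requires carrying the intermediate across the boundary
    assert first.totals["CP"] + second.totals["CP"] == pytest.approx(
        whole.totals["CP"], abs=1e-9
    )
    assert second.final_state.portions == pytest.approx(whole.totals["CP"], abs=1e-9)


def test_accumulate_tidy_export(constant_series):
    series = constant_series(5.0, 24)
    tidy = accumulate(series, dt.date(2019, 10, 1), dt.date(2019, 10, 1)).to_tidy()
    assert set(tidy.columns) == {"timestamp", "model", "hourly", "cumulative"}
    assert set(tidy["model"]) == {"CH", "CU", "CP", "GDH"}


# ---------------------------------------------------------------------------
# Daily extremes -> hourly
# ---------------------------------------------------------------------------


def _daily_frame(dates, tmin, tmax):
    return pd.DataFrame({"date": pd.to_datetime(dates), "tmin_c": tmin, "tmax_c": tmax})


def test_hourly_from_daily_constant_day():
    daily = _daily_frame(["2020-01-01"], [10.0], [10.0])
    series = hourly_from_daily(daily, latitude=40.0)
    assert len(series) == 24
    assert np.allclose(series.temps.to_numpy(), 10.0)


def test_equinox_daylength_near_12h():
    for lat in (-60.0, -35.0, 0.0, 38.85, 60.0):
        assert daylength(lat, 80) == pytest.approx(12.0, abs=0.2)
    # solstice contrast at mid latitude
    assert daylength(40.0, 172) > 14.0
    assert daylength(40.0, 355) < 10.0


def test_hourly_from_daily_recovers_extremes():
    rng = np.random.default_rng(5)
    n = 60
    base = 8.0 + 6.0 * np.sin(np.arange(n) / 9.0)
    tmin = base - 5.0 + rng.normal(0, 0.8, n)
    tmax = base + 5.0 + rng.normal(0, 0.8, n)
    daily = _daily_frame(pd.date_range("2019-11-01", periods=n), tmin, tmax)
    series = hourly_from_daily(daily, latitude=41.7)
    values = series.temps.to_numpy().reshape(n, 24)
    assert np.allclose(values.min(axis=1), tmin, atol=0.01)
    assert np.allclose(values.max(axis=1), tmax, atol=0.01)


def test_hourly_from_daily_single_day_matches_direct_formula():
    """Independent evaluation of the day-curve for one interior day."""
    tmin, tmax = 2.0, 14.0
    daily = _daily_frame(
        ["2020-01-09", "2020-01-10", "2020-01-11"],
        [tmin, tmin, tmin],
        [tmax, tmax, tmax],
    )
    lat = 40.0
    series = hourly_from_daily(daily, lat)
    got = series.temps.to_numpy()[24:48]

    doy = 10
    decl = math.radians(23.45) * math.sin(2 * math.pi * (284 + doy) / 365.0)
    cos_h0 = -math.tan(math.radians(lat)) * math.tan(decl)
    dl = 2 * math.degrees(math.acos(cos_h0)) / 15.0
    sunrise = 12.0 - dl / 2.0
    h_min = round(sunrise)
    h_max = round(sunrise + (dl + 4.0) / 2.0)
    night = h_min + 24 - h_max
    expected = []
    for h in range(24):
        if h < h_min:  # tail of the previous night's log decay
            expected.append(
                tmax - (tmax - tmin) * math.log(h + 24 - h_max + 1) / math.log(night + 1)
            )
        elif h <= h_max:  # quarter-sine rise
            expected.append(
                tmin + (tmax - tmin) * math.sin(0.5 * math.pi * (h - h_min) / (h_max - h_min))
            )
        else:  # log decay toward the next sunrise
            expected.append(
                tmax - (tmax - tmin) * math.log(h - h_max + 1) / math.log(night + 1)
            )
    assert np.allclose(got, expected, atol=1e-9)


def test_hourly_from_daily_rejects_bad_inputs():
    daily = _daily_frame(["2020-01-01"], [12.0], [10.0])
    with pytest.raises(ValueError, match="tmin exceeds tmax"):
        hourly_from_daily(daily, 40.0)
    good = _daily_frame(["2020-01-01"], [5.0], [10.0])
    with pytest.raises(ValueError, match="latitude"):
        hourly_from_daily(good, 70.0)


# ---------------------------------------------------------------------------
# Semi-hourly resampling
# ---------------------------------------------------------------------------


def test_resample_semihourly_means():
    index = pd.date_range("2020-01-01 00:00", periods=4, freq="30min")
    series = pd.Series([4.0, 6.0, 10.0, 12.0], index=index)
    hourly = resample_semihourly(series)
    assert np.allclose(hourly.temps.to_numpy(), [5.0, 11.0])


def test_resample_semihourly_constant_unchanged():
    index = pd.date_range("2020-01-01", periods=96, freq="30min")
    series = pd.Series(np.full(96, 7.5), index=index)
    hourly = resample_semihourly(series)
    assert np.allclose(hourly.temps.to_numpy(), 7.5)
    assert len(hourly) == 48


def test_resample_semihourly_fills_short_gap_linearly():
    index = pd.date_range("2020-01-01 00:00", periods=12, freq="30min")
    values = np.linspace(0.0, 11.0, 12)
    series = pd.Series(values, index=index).drop(index[4:8])  # 2 h gap
    hourly = resample_semihourly(series)
    # linear data stays linear through the interpolated gap
    assert np.allclose(hourly.temps.to_numpy(), [0.5, 2.5, 4.5, 6.5, 8.5, 10.5])


def test_resample_semihourly_rejects_long_gap():
    index = pd.date_range("2020-01-01 00:00", periods=48, freq="30min")
    series = pd.Series(np.arange(48.0), index=index).drop(index[10:25])  # 7.5 h gap
    with pytest.raises(ValueError, match="gap of 7.5 h"):
        resample_semihourly(series)


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=-20.0, max_value=45.0), min_size=10, max_size=200))
def test_cumulative_models_monotone_property(temps):
    arr = np.asarray(temps)
    assert (np.cumsum(thermal.chilling_hours(arr)) >= 0).all()
    hourly, _ = dynamic_portions(arr)
    assert (hourly >= 0).all()
    assert (thermal.gdh(arr) >= 0).all()
    cu = thermal.utah_units(arr)
    drops = np.nonzero(cu < 0)[0]
    assert np.all(arr[drops] >= 16.0)


def test_hourly_series_validation():
    index = pd.date_range("2020-01-01", periods=5, freq="2h")
    with pytest.raises(ValueError, match="1 h spacing"):
        HourlyTempSeries(pd.Series(np.zeros(5), index=index))
    good = pd.date_range("2020-01-01", periods=5, freq="h")
    with pytest.raises(ValueError, match="finite"):
        HourlyTempSeries(pd.Series([1, 2, np.nan, 4, 5], index=good))
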