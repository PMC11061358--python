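import datetime as dt

import numpy as np
import pandas as pd
import pytest

from plumchill import synthetic as syn
from plumchill.thermal import HourlyTempSeries


@pytest.fixture(scope="session")
def badajoz_record():
    """40-year Badajoz-like synthetic station record (daily + hourly)."""
    daily, hourly = syn.generate_station_record(syn.BADAJOZ_LIKE, 1981, 40)
    return daily, hourly


@pytest.fixture(scope="session")
def zaragoza_record():
    daily, hourly = syn.generate_station_record(syn.ZARAGOZA_LIKE, 1981, 40)
    return daily, hourly


@pytest.fixture()
def constant_series():
    """Helper building a constant-temperature hourly series."""

    def make(temp_c: float, n_hours: int = 24, start="2019-10-01") -> HourlyTempSeries:
        index = pd.date_range(start, periods=n_hours, freq="h")
        return HourlyTempSeries(pd.Series(np.full(n_hours, float(temp_c)), index=index))

    return make


@pytest.fixture()
def winter_series():
    """One synthetic dormancy season (Oct 1 – Mar 31) of hourly data."""
    spec = syn.SyntheticClimateSpec(
        annual_mean_c=15.0,
        seasonal_amplitude_c=8.0,
        diurnal_range_c=10.0,
        anomaly_autocorr=0.6,
        anomaly_sd_c=1.5,
        latitude=40.0,
        seed=7,
    )
    daily, hourly = syn.generate_station_record(spec, 2019, 2)
    return hourly
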