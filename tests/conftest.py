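import numpy as np
import pandas as pd
import pytest

from himax.aggregation import daily_summaries
from himax.synthetic_weather import RegimeSpec, SyntheticStationConfig, simulate_station


@pytest.fixture(scope="session")
def coupled_noisefree_cfg():
    """Three years, day-constant dew point, no hourly noise, no gaps."""
    return SyntheticStationConfig(
        n_years=3,
        noise_sd=0.0,
        td_noise_sd=0.0,
        missing_rate=0.0,
        regime_probs=(1.0, 0.0, 0.0),
        seed=101,
    )


@pytest.fixture(scope="session")
def coupled_noisefree_days(coupled_noisefree_cfg):
    return daily_summaries(simulate_station(coupled_noisefree_cfg))


@pytest.fixture(scope="session")
def surge_cfg():
    """Hot summer station where every day has an evening moisture surge."""
    return SyntheticStationConfig(
        n_years=1,
        tmin_mean=14.0,
        tmax_mean=23.0,
        noise_sd=0.0,
        td_noise_sd=0.0,
        synoptic_sd=0.0,
        missing_rate=0.0,
        regimes=(RegimeSpec("surge", surge_amplitude=12.0, surge_hour=18.0, surge_width=1.0),),
        regime_probs=(1.0,),
        dewpoint_depression=6.0,
        seed=202,
    )


@pytest.fixture(scope="session")
def surge_days(surge_cfg):
    return daily_summaries(simulate_station(surge_cfg))


@pytest.fixture(scope="session")
def mixture_days():
    """A warm station with the default regime mixture and noise levels."""
    cfg = SyntheticStationConfig(n_years=3, tmin_mean=14.0, tmax_mean=23.0, seed=303)
    return daily_summaries(simulate_station(cfg))


def _hourly_frame(hours, tas_c, rh, valid=None, date="2001-07-01"):
    """Build a minimal hourly-record frame for hand-constructed days."""
    base = pd.Timestamp(date)
    times = [base + pd.Timedelta(hours=int(h)) for h in hours]
    n = len(times)
    return pd.DataFrame(
        {
            "time": times,
            "tas_c": np.asarray(tas_c, dtype=float),
            "rh": np.asarray(rh, dtype=float),
            "valid": np.ones(n, dtype=bool) if valid is None else np.asarray(valid),
        }
    )


@pytest.fixture
def hourly_frame():
    """Factory fixture for hand-constructed hourly-record frames."""
    return _hourly_frame
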