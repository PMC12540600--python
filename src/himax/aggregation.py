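"""Hourly plumbing: capture-window extraction and the two daily-max workflows.

Two ways to obtain a day's maximum heat index from a station record:

* the *actual* workflow computes the heat index every hour and takes the
  daily maximum (``hismax24``), recording the hour at which it occurs;
* the *estimate* workflow evaluates the heat index once per day from the
  daily maximum temperature and daily minimum relative humidity
  (``hismaxest``) -- the only option when just daily extremes are archived.

Because RH at the hour of the temperature maximum can only be at or above
the daily minimum, and the heat index increases with RH at fixed
temperature (up to a known kink in the operational algorithm),
``hismaxest`` can match ``hismax24`` exactly or underestimate it, never
overestimate it.

Day boundaries are local standard time; extremum ties resolve to the
earliest hour so that the temporal-case taxonomy downstream is
well-defined.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .hi_core import celsius_to_fahrenheit, nws_heat_index

__all__ = ["capture_window_hourly", "daily_summaries", "DEFAULT_MIN_VALID_HOURS"]

logger = logging.getLogger(__name__)

#: complete-day rule: at least this many valid hours per calendar day
DEFAULT_MIN_VALID_HOURS = 18


def capture_window_hourly(subhourly: pd.DataFrame, window_minutes: int = 15) -> pd.DataFrame:
    """Reduce a sub-hourly record to one observation per clock hour.

    For each hour, the valid record whose timestamp is nearest the top of
    the hour (within ``window_minutes``) is selected; ties break toward the
    earlier record.  Hours in the spanned range with no candidate are
    emitted with ``valid=False``.  Input must be time-sorted.
    """
    if not subhourly["time"].is_monotonic_increasing:
        raise ValueError("sub-hourly records must be sorted by time")
    df = subhourly.loc[subhourly["valid"]].copy()
    if df.empty:
        raise ValueError("no valid sub-hourly records")
    df["hour"] = df["time"].dt.round("h")
    df["offset"] = (df["time"] - df["hour"]).abs()
    df = df[df["offset"] <= pd.Timedelta(minutes=window_minutes)]
    # nearest first; on equal offset the earlier timestamp wins
    df = df.sort_values(["hour", "offset", "time"], kind="stable")
    picked = df.groupby("hour", as_index=False).first()

    full = pd.date_range(picked["hour"].min(), picked["hour"].max(), freq="h")
    value_cols = [c for c in subhourly.columns if c not in ("time", "valid")]
    out = picked.set_index("hour").reindex(full)
    result = pd.DataFrame({"time": full})
    for c in value_cols:
        result[c] = out[c].to_numpy()
    result["valid"] = ~out["tas_c"].isna().to_numpy()
    return result


def daily_summaries(
    hourly: pd.DataFrame,
    hi_fn=None,
    min_valid_hours: int = DEFAULT_MIN_VALID_HOURS,
) -> pd.DataFrame:
    """Per-day extremes and both daily-maximum heat index workflows.

    Parameters
    ----------
    hourly:
        One station's hourly records (columns ``time``, ``tas_c``, ``rh``,
        ``valid``) in local standard time.
    hi_fn:
        Heat index function of (temp degF, RH percent) -> degF; defaults to
        the NWS algorithm.
    min_valid_hours:
        Days with fewer valid hours are kept but flagged ``complete=False``.

    Returns
    -------
    DataFrame with one row per calendar day that has any valid hour:
    ``date, tasmax_c, hour_tasmax, hursmin, hour_hursmin, hismax24_f,
    hour_hismax24, hismaxest_f, n_valid_hours, complete``.
    """
    hi_fn = hi_fn or nws_heat_index
    df = hourly.loc[hourly["valid"], ["time", "tas_c", "rh"]].copy()
    n_empty = hourly["time"].dt.normalize().nunique() - df["time"].dt.normalize().nunique()
    if n_empty:
        logger.info("omitting %d day(s) with no valid hours", n_empty)
    if df.empty:
        raise ValueError("no valid hourly records")
    df = df.sort_values("time", kind="stable").reset_index(drop=True)
    df["date"] = df["time"].dt.normalize()
    df["hour"] = df["time"].dt.hour
    df["hi_f"] = hi_fn(celsius_to_fahrenheit(df["tas_c"].to_numpy()), df["rh"].to_numpy())

    grp = df.groupby("date", sort=True)
    # idxmax/idxmin return the first occurrence, i.e. the earliest hour on ties
    i_tasmax = grp["tas_c"].idxmax()
    i_hursmin = grp["rh"].idxmin()
    i_himax = grp["hi_f"].idxmax()

    out = pd.DataFrame(
        {
            "date": i_tasmax.index,
            "tasmax_c": df.loc[i_tasmax, "tas_c"].to_numpy(),
            "hour_tasmax": df.loc[i_tasmax, "hour"].to_numpy(),
            "hursmin": df.loc[i_hursmin, "rh"].to_numpy(),
            "hour_hursmin": df.loc[i_hursmin, "hour"].to_numpy(),
            "hismax24_f": df.loc[i_himax, "hi_f"].to_numpy(),
            "hour_hismax24": df.loc[i_himax, "hour"].to_numpy(),
            "n_valid_hours": grp.size().to_numpy(),
        }
    ).reset_index(drop=True)
    out["hismaxest_f"] = hi_fn(
        celsius_to_fahrenheit(out["tasmax_c"].to_numpy()), out["hursmin"].to_numpy()
    )
    out["complete"] = out["n_valid_hours"] >= min_valid_hours
    return out
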