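"""Readers and writers for station formats, plus bundled reference tables.

Supported formats (layout versions pinned in the README):

* **ISD-Lite** fixed-width hourly files: whitespace-separated columns
  ``year month day hour temp dewpoint pressure wind_dir wind_speed
  sky_cond precip_1h precip_6h`` with temperature and dew point in tenths
  of a degree Celsius and ``-9999`` as the missing code.  Timestamps are
  UTC and are shifted to local standard time by a per-station fixed UTC
  offset.
* **USCRN sub-hourly** (subhourly01) column files: 5-minute records whose
  local-standard-time stamp, air temperature (degC) and integer relative
  humidity (percent) are taken from the documented column positions.

The writers emit synthetic series in the same layouts (with the stated
quantization: 0.1 degC for temperatures, integer percent for USCRN RH) so
the readers can be exercised round-trip without downloads.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .hi_core import dewpoint_to_rh

__all__ = [
    "StationMetadata",
    "read_isd_lite",
    "write_isd_lite",
    "read_uscrn_subhourly",
    "write_uscrn_subhourly",
    "load_station_summary",
    "STATION_SUMMARY_SHA256",
]

logger = logging.getLogger(__name__)

MISSING = -9999
STATION_SUMMARY_SHA256 = "d5ecf6591f0fe6e6f924a6062a6f9276e6450de03a89f2a21f96fd04eb4ae7bc"

# USCRN subhourly01 whitespace-separated column positions (0-based)
_USCRN_LST_DATE = 3
_USCRN_LST_TIME = 4
_USCRN_AIR_T = 8
_USCRN_RH = 15
_USCRN_NCOL = 23


@dataclass(frozen=True)
class StationMetadata:
    """Identity and location of one station."""

    code: str
    name: str = ""
    state: str = ""
    source: str = "ISD-lite"  # or "USCRN"
    latitude: float = 0.0
    longitude_w: float = 0.0
    elevation_m: float = 0.0
    utc_offset_hours: int = 0

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude outside [-90, 90]")


def read_isd_lite(path, utc_offset_hours: int = 0, strict: bool = False) -> pd.DataFrame:
    """Parse an ISD-Lite file into hourly records in local standard time.

    Returns columns ``time, tas_c, td_c, rh, valid``.  Malformed lines are
    skipped with a log entry (or raise when ``strict``).  Records with a
    missing temperature or dew point are kept with ``valid=False``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            try:
                y, m, d, h = (int(p) for p in parts[:4])
                temp, dew = int(parts[4]), int(parts[5])
                rows.append((y, m, d, h, temp, dew))
            except (ValueError, IndexError):
                if strict:
                    raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
                logger.warning("%s: skipping malformed line %d", path, lineno)
    if not rows:
        raise ValueError(f"{path}: no parseable records")
    arr = pd.DataFrame(rows, columns=["y", "m", "d", "h", "temp", "dew"])
    time_utc = pd.to_datetime(dict(year=arr.y, month=arr.m, day=arr.d, hour=arr.h))
    valid = (arr.temp != MISSING) & (arr.dew != MISSING)
    tas = np.where(valid, arr.temp / 10.0, np.nan)
    td = np.where(valid, arr.dew / 10.0, np.nan)
    rh = np.full(len(arr), np.nan)
    if valid.any():
        rh[valid.to_numpy()] = dewpoint_to_rh(tas[valid], td[valid])
    return pd.DataFrame(
        {
            "time": time_utc + pd.Timedelta(hours=utc_offset_hours),
            "tas_c": tas,
            "td_c": td,
            "rh": rh,
            "valid": valid.to_numpy(),
        }
    )


def write_isd_lite(df: pd.DataFrame, path, utc_offset_hours: int = 0) -> None:
    """Write hourly records (local standard time) in ISD-Lite layout (UTC)."""
    time_utc = df["time"] - pd.Timedelta(hours=utc_offset_hours)
    temp = np.where(df["valid"], np.round(df["tas_c"] * 10.0), MISSING).astype(int)
    dew = np.where(df["valid"], np.round(df["td_c"] * 10.0), MISSING).astype(int)
    with open(path, "w") as fh:
        for t, tv, dv in zip(time_utc, temp, dew):
            fh.write(
                f"{t.year:4d} {t.month:2d} {t.day:2d} {t.hour:2d} "
                f"{tv:5d} {dv:5d} {MISSING:5d} {MISSING:5d} {MISSING:5d} "
                f"{MISSING:5d} {MISSING:5d} {MISSING:5d}\n"
            )


def read_uscrn_subhourly(path, strict: bool = False) -> pd.DataFrame:
    """Parse a USCRN sub-hourly (5-minute) file.

    Timestamps are taken from the local-standard-time columns; returns
    ``time, tas_c, rh, valid``.  RH is an integer percentage in the source.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            try:
                if len(parts) < _USCRN_NCOL:
                    raise ValueError("short line")
                date, hhmm = parts[_USCRN_LST_DATE], parts[_USCRN_LST_TIME]
                tas = float(parts[_USCRN_AIR_T])
                rh = float(parts[_USCRN_RH])
                rows.append((date, hhmm, tas, rh))
            except (ValueError, IndexError):
                if strict:
                    raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
                logger.warning("%s: skipping malformed line %d", path, lineno)
    if not rows:
        raise ValueError(f"{path}: no parseable records")
    df = pd.DataFrame(rows, columns=["date", "hhmm", "tas_c", "rh"])
    time = pd.to_datetime(df["date"] + df["hhmm"].str.zfill(4), format="%Y%m%d%H%M")
    valid = (df["tas_c"] > MISSING / 10) & (df["rh"] >= 0.0) & (df["rh"] <= 100.0)
    return pd.DataFrame(
        {
            "time": time,
            "tas_c": df["tas_c"].where(valid).to_numpy(),
            "rh": df["rh"].where(valid).to_numpy(),
            "valid": valid.to_numpy(),
        }
    )


def write_uscrn_subhourly(df: pd.DataFrame, path, meta: StationMetadata | None = None,
                          wban: str = "99999") -> None:
    """Write 5-minute records in the USCRN subhourly01 column layout."""
    lat = meta.latitude if meta else 0.0
    lon = -meta.longitude_w if meta else 0.0
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            t = row["time"]
            tas = round(row["tas_c"], 1) if row["valid"] else MISSING / 10
            rh = int(round(row["rh"])) if row["valid"] else MISSING
            fh.write(
                f"{wban} {t:%Y%m%d} {t:%H%M} {t:%Y%m%d} {t:%H%M} 1.000 "
                f"{lon:8.2f} {lat:8.2f} {tas:7.1f} 0.0 0 0 {tas:7.1f} R 0 "
                f"{rh:5d} 0 -99.000 -9999.0 990 0 1.50 0\n"
            )


def load_station_summary(verify_checksum: bool = True) -> pd.DataFrame:
    """Load the bundled 37-station summary table.

    Percentage columns are converted to fractions: ``underestimation`` and
    ``out_of_range`` in [0, 1].  Thresholds stay in degF.
    """
    data = resources.files("himax.data").joinpath("station_summary_s1.csv").read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(data).hexdigest()
        if digest != STATION_SUMMARY_SHA256:
            raise ValueError("station summary fixture failed its checksum")
    from io import BytesIO

    df = pd.read_csv(BytesIO(data))
    df["underestimation"] = df["underestimation_pct"] / 100.0
    df["out_of_range"] = df["out_of_range_pct"] / 100.0
    df["missing_fraction"] = df["missing_pct"] / 100.0
    return df
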