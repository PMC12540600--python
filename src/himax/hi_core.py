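"""NWS heat index, unit and humidity conversions, and Steadman-range screening.

The heat index (HI) is the U.S. National Weather Service "apparent
temperature": what a shaded, lightly breezy environment feels like to an
idealized adult, given air temperature and relative humidity.  Operationally
the NWS evaluates a polynomial fit (Rothfusz 1990) to Steadman's (1979)
thermoregulation model, with two piecewise adjustments and a simple linear
fallback in mild conditions:

1. ``T <= 40 degF`` -- HI is defined to equal the air temperature.
2. Otherwise the simple formula
   ``0.5 * (T + 61.0 + (T - 68.0)*1.2 + RH*0.094)``
   is evaluated; if its mean with ``T`` is below 80 degF it is the result.
3. Otherwise the nine-term Rothfusz regression applies, minus a dry
   adjustment when ``RH < 13%`` and ``80 <= T <= 112 degF``, plus a humid
   adjustment when ``RH > 85%`` and ``80 <= T <= 87 degF``.

This is the procedure published by the NWS Weather Prediction Center
(https://www.wpc.ncep.noaa.gov/html/heatindex_equation.shtml).  Note that
the hand-off between steps 2 and 3 is discontinuous: near ``T ~ 81 degF``
at low humidity the surface can *drop* by about 1 degF as RH rises across
the branch switch.  That kink is a property of the operational algorithm,
not of this implementation; see ``docs/methods.md``.

All HI computation happens on the Fahrenheit scale; helpers are provided
for Celsius callers.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np

__all__ = [
    "fahrenheit_to_celsius",
    "celsius_to_fahrenheit",
    "convert_temperature",
    "nws_heat_index",
    "heat_index_celsius",
    "saturation_vapor_pressure",
    "dewpoint_to_rh",
    "steadman_range_check",
    "load_steadman_polygon",
    "MAGNUS_A",
    "MAGNUS_B",
    "MAGNUS_ES0",
]

# Magnus saturation vapor pressure constants (Alduchov & Eskridge 1996),
# accurate over roughly -40..60 degC.  es(T) = ES0 * exp(A*T / (B + T)).
MAGNUS_A = 17.625
MAGNUS_B = 243.04  # degC
MAGNUS_ES0 = 6.1094  # hPa


def fahrenheit_to_celsius(value):
    """Convert degrees Fahrenheit to degrees Celsius."""
    return (np.asarray(value, dtype=float) - 32.0) / 1.8


def celsius_to_fahrenheit(value):
    """Convert degrees Celsius to degrees Fahrenheit."""
    return np.asarray(value, dtype=float) * 1.8 + 32.0


def convert_temperature(value, from_scale: str, to_scale: str):
    """Affine conversion between the 'F' and 'C' temperature scales."""
    scales = {"F", "C"}
    if from_scale not in scales or to_scale not in scales:
        raise ValueError(
            f"unknown temperature scale in ({from_scale!r}, {to_scale!r}); "
            "expected 'F' or 'C'"
        )
    if from_scale == to_scale:
        return np.asarray(value, dtype=float)
    if from_scale == "C":
        return celsius_to_fahrenheit(value)
    return fahrenheit_to_celsius(value)


def _rothfusz(t, rh):
    """Nine-term Rothfusz (1990) regression in degF / percent."""
    return (
        -42.379
        + 2.04901523 * t
        + 10.14333127 * rh
        - 0.22475541 * t * rh
        - 0.00683783 * t * t
        - 0.05481717 * rh * rh
        + 0.00122874 * t * t * rh
        + 0.00085282 * t * rh * rh
        - 0.00000199 * t * t * rh * rh
    )


def nws_heat_index(temp_f, rh):
    """NWS heat index in degF from temperature (degF) and RH (percent).

    Vectorized over array inputs.  Raises ``ValueError`` on non-finite
    input or relative humidity outside [0, 100].

    Examples
    --------
    >>> float(nws_heat_index(40.0, 80.0))
    40.0
    """
    t = np.asarray(temp_f, dtype=float)
    r = np.asarray(rh, dtype=float)
    t, r = np.broadcast_arrays(t, r)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise ValueError("non-finite temperature or relative humidity")
    if np.any(r < 0.0) or np.any(r > 100.0):
        raise ValueError("relative humidity outside [0, 100] percent")

    simple = 0.5 * (t + 61.0 + (t - 68.0) * 1.2 + r * 0.094)
    hi = np.where(t <= 40.0, t, simple)

    # Full regression whenever the simple value averaged with T reaches 80 F.
    roth_mask = (t > 40.0) & ((simple + t) / 2.0 >= 80.0)
    roth = _rothfusz(t, r)

    dry = roth_mask & (r < 13.0) & (t >= 80.0) & (t <= 112.0)
    # (17 - |T-95|)/17 is non-negative throughout the dry-adjustment window.
    dry_term = np.sqrt(np.clip((17.0 - np.abs(t - 95.0)) / 17.0, 0.0, None))
    roth = np.where(dry, roth - ((13.0 - r) / 4.0) * dry_term, roth)

    humid = roth_mask & (r > 85.0) & (t >= 80.0) & (t <= 87.0)
    roth = np.where(humid, roth + ((r - 85.0) / 10.0) * ((87.0 - t) / 5.0), roth)

    hi = np.where(roth_mask, roth, hi)
    if np.isscalar(temp_f) and np.isscalar(rh):
        return float(hi)
    return hi


def heat_index_celsius(temp_c, rh):
    """NWS heat index in degC from temperature in degC and RH in percent."""
    return fahrenheit_to_celsius(nws_heat_index(celsius_to_fahrenheit(temp_c), rh))


def saturation_vapor_pressure(temp_c, *, a: float = MAGNUS_A, b: float = MAGNUS_B,
                              es0: float = MAGNUS_ES0):
    """Magnus saturation vapor pressure in hPa at temperature ``temp_c`` (degC).

    The default constants are the Alduchov-Eskridge set; alternative sets
    can be supplied through ``a``, ``b`` and ``es0``.
    """
    t = np.asarray(temp_c, dtype=float)
    return es0 * np.exp(a * t / (b + t))


def dewpoint_to_rh(temp_c, dewpoint_c, *, tolerance_c: float = 0.5):
    """Relative humidity (percent) from air and dew-point temperature (degC).

    RH = 100 * es(Td) / es(T) with the Magnus form.  A dew point exceeding
    the air temperature by at most ``tolerance_c`` (instrument noise) is
    clipped to saturation with a warning; larger excesses raise
    ``ValueError``.  Results are clipped to [0, 100].
    """
    t = np.asarray(temp_c, dtype=float)
    td = np.asarray(dewpoint_c, dtype=float)
    t, td = np.broadcast_arrays(t, td)
    excess = td - t
    with np.errstate(invalid="ignore"):
        if np.any(excess > tolerance_c):
            raise ValueError(
                f"dew point exceeds air temperature by more than {tolerance_c} degC"
            )
        if np.any(excess > 0.0):
            warnings.warn(
                "dew point marginally exceeds air temperature; clipping to saturation",
                stacklevel=2,
            )
    td = np.minimum(td, t)
    rh = 100.0 * saturation_vapor_pressure(td) / saturation_vapor_pressure(t)
    rh = np.clip(rh, 0.0, 100.0)
    if np.isscalar(temp_c) and np.isscalar(dewpoint_c):
        return float(rh)
    return rh


def load_steadman_polygon():
    """Load the (temperature degF, maximum valid RH percent) boundary table.

    The table ships as editable package data.  It is a best-effort
    approximation of the hot-humid region where Steadman's (1979)
    thermoregulation model stops being physical; the published studies that
    discuss the breakdown do not print an exact boundary.
    """
    with resources.files("himax.data").joinpath("steadman_validity.csv").open() as fh:
        rows = [
            line.split(",") for line in fh.read().splitlines()
            if line and not line.startswith("#")
        ]
    arr = np.array(rows[1:], dtype=float)  # skip header
    return arr[:, 0], arr[:, 1]


def steadman_range_check(temp_f, rh):
    """True where (T, RH) lies inside the adopted Steadman validity region.

    Mild and dry conditions are always in range; the boundary only excludes
    extremely hot *and* humid combinations, where the underlying
    thermoregulation model has no physical solution.  Temperatures beyond
    the table are held at the last tabulated RH limit.
    """
    t = np.asarray(temp_f, dtype=float)
    r = np.asarray(rh, dtype=float)
    temps, rh_max = load_steadman_polygon()
    limit = np.interp(t, temps, rh_max)
    inside = r <= limit
    if np.isscalar(temp_f) and np.isscalar(rh):
        return bool(inside)
    return inside
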