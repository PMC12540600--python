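"""Two-part model of extreme-heat-day underestimation vs. local HI threshold.

Across stations, the fraction of true extreme heat days missed by the
daily-extremes estimate grows nonlinearly with the local JJA 95th-percentile
heat index.  The model is piecewise in the threshold ``h`` (degF):

* below the 80 degF breakpoint (the NWS 'Caution' floor) the
  underestimation is a constant ``c`` -- the mean observed ratio over
  stations with thresholds under 80 degF;
* at and above 80 degF it follows the one-parameter exponential
  ``r(h) = c * exp(k * (h - 80))``, the minimal family that is continuous
  with the flat branch at the breakpoint.

``k`` is fitted by least squares on the ratio scale (optionally the log
scale) over stations at or above the breakpoint.  Predictions are clipped
to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.optimize import minimize_scalar

__all__ = ["TwoPartModel", "fit_two_part", "apply_to_grid", "BREAKPOINT_F"]

BREAKPOINT_F = 80.0  # 26.67 degC

_F_UNITS = {"degf", "f", "fahrenheit", "degree_fahrenheit", "degrees_fahrenheit", "°f"}


@dataclass(frozen=True)
class TwoPartModel:
    """Constant-below / exponential-above model of the underestimation ratio."""

    c: float
    k: float
    h0: float = BREAKPOINT_F

    @property
    def c_reported(self) -> float:
        """The constant level rounded to 2 decimals, as reported."""
        return round(self.c, 2)

    def predict(self, threshold_f):
        """Underestimation fraction at threshold(s) ``threshold_f`` (degF)."""
        h = np.asarray(threshold_f, dtype=float)
        r = np.where(h < self.h0, self.c, self.c * np.exp(self.k * (h - self.h0)))
        r = np.clip(r, 0.0, 1.0)
        r = np.where(np.isnan(h), np.nan, r)
        if np.isscalar(threshold_f):
            return float(r)
        return r


def fit_two_part(
    rows: pd.DataFrame,
    h0: float = BREAKPOINT_F,
    loss: str = "ratio",
    k_bounds: tuple[float, float] = (-0.5, 0.5),
) -> TwoPartModel:
    """Fit the two-part model to station summary rows.

    Parameters
    ----------
    rows:
        DataFrame with columns ``hismax24_threshold_f`` and
        ``underestimation`` (fractions in [0, 1]).
    h0:
        Breakpoint in degF (default 80).
    loss:
        'ratio' (default) minimizes squared residuals of the fractions;
        'log' minimizes squared residuals of log fractions.

    Requires at least one station below ``h0`` (to set the constant) and at
    least three at or above it (to fit the rate).
    """
    h = rows["hismax24_threshold_f"].to_numpy(dtype=float)
    r = rows["underestimation"].to_numpy(dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("underestimation values must be fractions in [0, 1]")
    below, above = h < h0, h >= h0
    if below.sum() < 1:
        raise ValueError("fit error: no stations below the breakpoint to set the constant")
    c = float(np.mean(r[below]))
    if above.sum() < 3:
        raise ValueError("fit error: fewer than 3 stations at/above the breakpoint "
                         "to fit the exponential rate")

    ha, ra = h[above], r[above]

    if loss == "ratio":
        def objective(k):
            return float(np.sum((ra - c * np.exp(k * (ha - h0))) ** 2))
    elif loss == "log":
        ra_pos = np.maximum(ra, 1e-6)

        def objective(k):
            return float(np.sum((np.log(ra_pos) - (np.log(c) + k * (ha - h0))) ** 2))
    else:
        raise ValueError("loss must be 'ratio' or 'log'")

    res = minimize_scalar(objective, bounds=k_bounds, method="bounded",
                          options={"xatol": 1e-10})
    return TwoPartModel(c=c, k=float(res.x), h0=h0)


def apply_to_grid(model: TwoPartModel, threshold_field: xr.DataArray,
                  offset_f: float = 0.0) -> xr.DataArray:
    """Predict the underestimation ratio over a gridded threshold field.

    ``threshold_field`` must carry a Fahrenheit ``units`` attribute.
    ``offset_f`` is a configurable bias adjustment added to the thresholds
    before prediction (a stand-in for dataset-specific calibrations).
    Missing cells propagate as NaN.
    """
    units = str(threshold_field.attrs.get("units", "")).lower()
    if units not in _F_UNITS:
        raise ValueError(
            "threshold field must declare Fahrenheit units "
            f"(units attribute {threshold_field.attrs.get('units')!r})"
        )
    out = xr.apply_ufunc(model.predict, threshold_field + offset_f)
    out.attrs = {
        "units": "1",
        "long_name": "predicted underestimation ratio of extreme heat days",
    }
    out.name = "underestimation_ratio"
    return out
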