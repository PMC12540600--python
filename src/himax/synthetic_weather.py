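"""Synthetic multi-year station weather with controllable diurnal coupling.

The generator emulates the single feature of real station records that the
daily-maximum heat index comparison is sensitive to: *where in the day* the
temperature peak, the relative-humidity minimum and the heat-index peak
fall relative to each other.  Three per-day moisture regimes control this:

``coupled``
    Day-constant dew point.  RH is then a monotone decreasing function of
    temperature, so the RH minimum co-occurs with the temperature maximum
    and the estimate from daily extremes matches the true hourly maximum.
``surge``
    An afternoon/evening logistic dew-point ramp (sea-breeze or outflow
    moisture surge).  With enough amplitude the heat-index peak decouples
    from the temperature peak and moves into the evening.
``drydown``
    A midday Gaussian dew-point dip (boundary-layer mixing), which can
    shift the RH minimum off the temperature peak.

Temperature is a seasonal baseline plus a raised-cosine diurnal cycle plus
AR(1) noise; dew point rides the daily baseline with its own AR(1) noise.
A fixed seed fully determines the output, including at 5-minute resolution,
where the deterministic signal is evaluated at each timestamp and the
hourly noise is linearly interpolated so that sampling the 5-minute series
at minute zero reproduces the hourly series exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hi_core import dewpoint_to_rh

__all__ = [
    "RegimeSpec",
    "SyntheticStationConfig",
    "simulate_station",
    "simulate_network",
    "simulate_summary_rows",
]

_KINDS = ("coupled", "surge", "drydown")


@dataclass(frozen=True)
class RegimeSpec:
    """One diurnal temperature-moisture coupling regime.

    Parameters
    ----------
    kind:
        'coupled', 'surge' or 'drydown'.
    base_dewpoint:
        Day-constant dew-point baseline in degC, or None to track the
        day's minimum temperature minus the station's dew-point depression.
    surge_amplitude:
        Dew-point rise (surge) or dip depth (drydown) in degC.
    surge_hour:
        Local hour at which the logistic surge is centred.
    surge_width:
        Logistic/Gaussian time scale in hours.
    """

    kind: str
    base_dewpoint: float | None = None
    surge_amplitude: float = 12.0
    surge_hour: float = 18.0
    surge_width: float = 1.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown regime kind {self.kind!r}; expected one of {_KINDS}")
        if self.surge_amplitude < 0:
            raise ValueError("surge_amplitude must be non-negative")
        if not 0 <= self.surge_hour < 24:
            raise ValueError("surge_hour must lie in [0, 24)")


def _default_regimes():
    return (
        RegimeSpec("coupled"),
        RegimeSpec("surge"),
        RegimeSpec("drydown", surge_amplitude=5.0),
    )


@dataclass(frozen=True)
class SyntheticStationConfig:
    """Configuration of one synthetic station.

    Seasonal means/amplitudes describe the annual cycle of daily Tmin/Tmax
    (degC); the diurnal cycle is a raised cosine peaking at ``peak_hour``.
    ``regime_probs`` mixes the moisture regimes day by day.  AR(1) noise
    (hourly) and an AR(1) synoptic anomaly (daily, shared by Tmin/Tmax)
    provide realistic variability; ``seed`` fully determines the output.
    """

    n_years: int = 3
    start_year: int = 2001
    tmin_mean: float = 10.0
    tmin_amplitude: float = 11.0
    tmax_mean: float = 19.0
    tmax_amplitude: float = 13.0
    peak_hour: float = 14.0
    peak_doy: float = 200.0
    regimes: tuple[RegimeSpec, ...] = field(default_factory=_default_regimes)
    regime_probs: tuple[float, ...] = (0.7, 0.2, 0.1)
    dewpoint_depression: float = 3.0
    noise_sd: float = 0.6
    td_noise_sd: float = 1.5
    noise_rho: float = 0.8
    synoptic_sd: float = 2.0
    synoptic_rho: float = 0.7
    missing_rate: float = 0.02
    outage_rate: float = 0.0
    outage_length_hours: int = 24
    seed: int = 0

    def __post_init__(self):
        if len(self.regimes) != len(self.regime_probs):
            raise ValueError("regimes and regime_probs length mismatch")
        if abs(sum(self.regime_probs) - 1.0) > 1e-9:
            raise ValueError("regime_probs must sum to 1")
        if self.n_years < 1:
            raise ValueError("n_years must be at least 1")


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series of length n with marginal sd and lag-1 rho."""
    if sd == 0.0 or n == 0:
        # Draw anyway so the stream position is independent of sd.
        rng.standard_normal(n)
        return np.zeros(n)
    eps = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = eps[0]
    scale = np.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + scale * eps[i]
    return sd * out


def simulate_station(cfg: SyntheticStationConfig, freq: str = "h") -> pd.DataFrame:
    """Generate one station's series at hourly ('h') or 5-minute ('5min') cadence.

    Returns a DataFrame with columns ``time`` (local standard time),
    ``tas_c``, ``td_c``, ``rh`` and ``valid``.  Invalid records keep their
    generated values; downstream consumers must honour the flag.
    """
    if freq not in ("h", "5min"):
        raise ValueError("freq must be 'h' or '5min'")
    rng = np.random.default_rng(cfg.seed)

    start = pd.Timestamp(f"{cfg.start_year}-01-01")
    end = pd.Timestamp(f"{cfg.start_year + cfg.n_years}-01-01")
    hours = pd.date_range(start, end, freq="h", inclusive="left")
    n_hours = len(hours)
    n_days = n_hours // 24

    # --- daily draws (independent of output cadence) ---
    regime_idx = rng.choice(len(cfg.regimes), size=n_days, p=list(cfg.regime_probs))
    synoptic = _ar1(rng, n_days, cfg.synoptic_sd, cfg.synoptic_rho)
    doy = np.arange(n_days) % 365.25
    seasonal = np.cos(2.0 * np.pi * (doy - cfg.peak_doy) / 365.25)
    tmin_d = cfg.tmin_mean + cfg.tmin_amplitude * seasonal + synoptic
    tmax_d = cfg.tmax_mean + cfg.tmax_amplitude * seasonal + synoptic
    tmax_d = np.maximum(tmax_d, tmin_d + 0.5)

    base_td = np.empty(n_days)
    for i, spec in enumerate(cfg.regimes):
        sel = regime_idx == i
        if spec.base_dewpoint is None:
            base_td[sel] = tmin_d[sel] - cfg.dewpoint_depression
        else:
            if np.any(spec.base_dewpoint >= tmin_d[sel]):
                raise ValueError(
                    f"regime {spec.kind!r}: base_dewpoint {spec.base_dewpoint} degC "
                    "is not below the daily minimum temperature"
                )
            base_td[sel] = spec.base_dewpoint

    # --- hourly draws ---
    t_noise = _ar1(rng, n_hours, cfg.noise_sd, cfg.noise_rho)
    td_noise = _ar1(rng, n_hours, cfg.td_noise_sd, cfg.noise_rho)
    missing = rng.random(n_hours) < cfg.missing_rate
    if cfg.outage_rate > 0.0:
        starts = np.flatnonzero(rng.random(n_hours) < cfg.outage_rate / cfg.outage_length_hours)
        for s in starts:
            missing[s:s + cfg.outage_length_hours] = True

    # --- evaluate on the requested time axis ---
    times = pd.date_range(start, end, freq=freq, inclusive="left")
    hour_float = (times - start) / pd.Timedelta("1h")
    day_of = np.minimum((hour_float // 24).astype(int), n_days - 1)
    local_hour = times.hour + times.minute / 60.0

    shape = 0.5 * (1.0 + np.cos(2.0 * np.pi * (local_hour - cfg.peak_hour) / 24.0))
    tas = tmin_d[day_of] + (tmax_d[day_of] - tmin_d[day_of]) * shape

    td = base_td[day_of].copy()
    for i, spec in enumerate(cfg.regimes):
        sel = regime_idx[day_of] == i
        if spec.kind == "surge":
            ramp = 1.0 / (1.0 + np.exp(-(local_hour[sel] - spec.surge_hour) / spec.surge_width))
            td[sel] = td[sel] + spec.surge_amplitude * ramp
        elif spec.kind == "drydown":
            dip = np.exp(-0.5 * ((local_hour[sel] - cfg.peak_hour) / max(spec.surge_width, 1e-6)) ** 2)
            td[sel] = td[sel] - spec.surge_amplitude * dip

    knots = np.arange(n_hours, dtype=float)
    tas = tas + np.interp(hour_float, knots, t_noise)
    td = td + np.interp(hour_float, knots, td_noise)
    td = np.minimum(td, tas)

    rh = dewpoint_to_rh(tas, td)
    if freq == "5min":
        # a sub-hourly record inherits the validity of its containing hour
        valid = ~missing[np.minimum(hour_float.astype(int), n_hours - 1)]
    else:
        valid = ~missing

    out = pd.DataFrame(
        {"time": times, "tas_c": tas, "td_c": td, "rh": rh, "valid": valid}
    )
    out.attrs["config"] = cfg
    return out


def simulate_network(
    n_stations: int,
    heat_gradient: tuple[float, float] = (-11.0, 3.0),
    moisture_gradient: tuple[float, float] = (-3.0, 2.5),
    template: SyntheticStationConfig | None = None,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Simulate a network whose stations sweep a cool->hot-humid gradient.

    Station ``i`` shifts the template's Tmin/Tmax means by a warmth offset
    interpolated along ``heat_gradient`` (degC) and reduces the dew-point
    depression by ``moisture_gradient`` (degC), so JJA heat-index
    thresholds span a range straddling 80 degF.  Each station gets its own
    child seed derived from ``seed``.
    """
    if n_stations < 2:
        raise ValueError("n_stations must be at least 2")
    template = template or SyntheticStationConfig()
    warm = np.linspace(heat_gradient[0], heat_gradient[1], n_stations)
    moist = np.linspace(moisture_gradient[0], moisture_gradient[1], n_stations)
    children = np.random.SeedSequence(seed).spawn(n_stations)
    out: dict[str, pd.DataFrame] = {}
    for i in range(n_stations):
        cfg = replace(
            template,
            tmin_mean=template.tmin_mean + warm[i],
            tmax_mean=template.tmax_mean + warm[i],
            dewpoint_depression=max(0.5, template.dewpoint_depression - moist[i]),
            seed=int(children[i].generate_state(1)[0] % (2**31)),
        )
        out[f"SYN{i:02d}"] = simulate_station(cfg)
    return out


def simulate_summary_rows(
    c: float,
    k: float,
    n_above: int = 30,
    n_below: int = 4,
    h_above: tuple[float, float] = (81.0, 110.0),
    h_below: tuple[float, float] = (67.0, 78.0),
    noise_sd: float = 0.02,
    h0: float = 80.0,
    seed: int = 0,
) -> "pd.DataFrame":
    """Station-summary rows drawn from a known two-part underestimation law.

    Thresholds are spread uniformly over ``h_below``/``h_above`` (degF);
    ratios are ``c`` below the breakpoint and ``c*exp(k*(h-h0))`` above,
    plus Gaussian noise of sd ``noise_sd``, clipped to [0, 1].  Used for
    parameter-recovery experiments on the two-part model fit.
    """
    rng = np.random.default_rng(seed)
    hb = np.linspace(h_below[0], h_below[1], n_below)
    ha = np.linspace(h_above[0], h_above[1], n_above)
    rb = c + rng.normal(0.0, noise_sd, n_below)
    ra = c * np.exp(k * (ha - h0)) + rng.normal(0.0, noise_sd, n_above)
    return pd.DataFrame(
        {
            "station_code": [f"SIM{i:02d}" for i in range(n_below + n_above)],
            "hismax24_threshold_f": np.concatenate([hb, ha]),
            "underestimation": np.clip(np.concatenate([rb, ra]), 0.0, 1.0),
        }
    )
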