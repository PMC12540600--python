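"""Comparison of the estimated and true daily-maximum heat index.

Implements the two evaluation procedures used to judge the daily-extremes
approximation against the hourly truth, plus the NWS warning-category day
counts and the temporal-coincidence taxonomy:

* *direct comparison* -- over heat-season (May-September) complete days,
  how often the estimate matches the truth exactly and how the remaining
  differences distribute over degree-Fahrenheit bins;
* *threshold-based comparison* -- extreme heat days are days whose daily
  maximum heat index exceeds the station's climatological 95th percentile
  of ``hismax24`` over June-August; the underestimation ratio is the
  fraction of true extreme days the estimate misses;
* *temporal cases* -- case 1: the heat-index peak hour coincides with the
  RH-minimum hour; case 2: it coincides with the temperature-maximum hour
  only; case 3: with neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdClimatology",
    "UnderestimationResult",
    "DirectComparison",
    "ComparisonReport",
    "jja_threshold",
    "direct_compare",
    "underestimation_ratio",
    "nws_category_counts",
    "temporal_case_classify",
    "compare_station",
    "report_frame",
    "HEAT_SEASON_MONTHS",
    "NWS_CATEGORIES",
    "DIFF_BIN_LABELS",
]

HEAT_SEASON_MONTHS = (5, 6, 7, 8, 9)  # MJJAS
JJA_MONTHS = (6, 7, 8)
#: NWS warning categories, half-open [lower, upper) in degF
NWS_CATEGORIES = {
    "Caution": (80.0, 90.0),
    "Extreme Caution": (90.0, 103.0),
    "Danger": (103.0, 125.0),
    "Extreme Danger": (125.0, np.inf),
}
DIFF_BIN_LABELS = ("0", "(0,1]", "(1,2]", "(2,3]", ">3")


@dataclass(frozen=True)
class ThresholdClimatology:
    """A station's JJA 95th-percentile hismax24 climatology (degF)."""

    station: str
    value_f: float
    period: tuple[int, int] | None = None


@dataclass(frozen=True)
class DirectComparison:
    exact_fraction: float
    bin_fractions: dict[str, float]
    n_days: int


@dataclass(frozen=True)
class UnderestimationResult:
    n24_extreme_days: int
    nest_extreme_days: int
    ratio: float  # NaN when no true extreme days exist


@dataclass
class ComparisonReport:
    station: str
    threshold_f: float
    direct: DirectComparison
    underestimation: UnderestimationResult
    case_fractions: dict[int, float]
    category_counts_his24: dict[str, int] = field(default_factory=dict)
    category_counts_hisest: dict[str, int] = field(default_factory=dict)


def _complete(days: pd.DataFrame) -> pd.DataFrame:
    return days.loc[days["complete"]]


def jja_threshold(days: pd.DataFrame, period: tuple[int, int] | None = None,
                  station: str = "") -> ThresholdClimatology:
    """95th percentile of hismax24 over complete JJA days (linear interpolation).

    ``period`` optionally restricts to reference years [first, last].
    """
    d = _complete(days)
    if period is not None:
        years = pd.DatetimeIndex(d["date"]).year
        d = d.loc[(years >= period[0]) & (years <= period[1])]
    d = d.loc[pd.DatetimeIndex(d["date"]).month.isin(JJA_MONTHS)]
    if d.empty:
        raise ValueError("no complete JJA days in the reference period")
    value = float(np.percentile(d["hismax24_f"].to_numpy(), 95.0))
    return ThresholdClimatology(station=station, value_f=value, period=period)


def direct_compare(
    days: pd.DataFrame,
    season_months: tuple[int, ...] = HEAT_SEASON_MONTHS,
    atol_f: float = 1e-6,
) -> DirectComparison:
    """Exact-match and difference-bin fractions over heat-season complete days.

    Differences ``hismax24 - hismaxest`` (degF) fall into the bins
    {0}, (0,1], (1,2], (2,3], >3; the exact bin uses tolerance ``atol_f``
    to absorb floating-point noise.  Fractions sum to 1.
    """
    d = _complete(days)
    d = d.loc[pd.DatetimeIndex(d["date"]).month.isin(season_months)]
    if d.empty:
        raise ValueError("no complete heat-season days to compare")
    diff = (d["hismax24_f"] - d["hismaxest_f"]).to_numpy()
    n = len(diff)
    exact = np.abs(diff) <= atol_f
    edges = [(0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, np.inf)]
    fracs = {"0": float(exact.sum()) / n}
    rest = diff[~exact]
    for (lo, hi), label in zip(edges, DIFF_BIN_LABELS[1:]):
        fracs[label] = float(((rest > lo) & (rest <= hi)).sum()) / n
    return DirectComparison(exact_fraction=fracs["0"], bin_fractions=fracs, n_days=n)


def underestimation_ratio(days: pd.DataFrame, threshold_f: float) -> UnderestimationResult:
    """Fraction of true extreme heat days missed by the estimate.

    Extreme-day membership is strict exceedance of the threshold; all
    complete days of the year qualify.  The ratio (N24 - Nest) / N24 is NaN
    when no true extreme day exists.
    """
    d = _complete(days)
    n24 = int((d["hismax24_f"] > threshold_f).sum())
    nest = int((d["hismaxest_f"] > threshold_f).sum())
    ratio = float("nan") if n24 == 0 else (n24 - nest) / n24
    return UnderestimationResult(n24, nest, ratio)


def nws_category_counts(values_f) -> dict[str, int]:
    """Day counts per NWS warning category; values below 80 degF are uncounted."""
    v = np.asarray(values_f, dtype=float)
    return {
        name: int(((v >= lo) & (v < hi)).sum())
        for name, (lo, hi) in NWS_CATEGORIES.items()
    }


def temporal_case_classify(days: pd.DataFrame) -> np.ndarray:
    """Classify each (complete) day into temporal case 1, 2 or 3.

    Case 1 when the hismax24 hour equals the hursmin hour; case 2 when it
    equals the tasmax hour only; case 3 otherwise.
    """
    h24 = days["hour_hismax24"].to_numpy()
    hrh = days["hour_hursmin"].to_numpy()
    ht = days["hour_tasmax"].to_numpy()
    return np.where(h24 == hrh, 1, np.where(h24 == ht, 2, 3))


def compare_station(
    days: pd.DataFrame,
    station: str = "",
    period: tuple[int, int] | None = None,
    season_months: tuple[int, ...] = HEAT_SEASON_MONTHS,
    atol_f: float = 1e-6,
) -> ComparisonReport:
    """Assemble the full per-station comparison report."""
    thr = jja_threshold(days, period=period, station=station)
    direct = direct_compare(days, season_months=season_months, atol_f=atol_f)
    under = underestimation_ratio(days, thr.value_f)
    season = _complete(days)
    season = season.loc[pd.DatetimeIndex(season["date"]).month.isin(season_months)]
    cases = temporal_case_classify(season)
    n = len(cases)
    case_fractions = {c: float((cases == c).sum()) / n for c in (1, 2, 3)}
    return ComparisonReport(
        station=station,
        threshold_f=thr.value_f,
        direct=direct,
        underestimation=under,
        case_fractions=case_fractions,
        category_counts_his24=nws_category_counts(_complete(days)["hismax24_f"]),
        category_counts_hisest=nws_category_counts(_complete(days)["hismaxest_f"]),
    )


def report_frame(reports: dict[str, ComparisonReport]) -> pd.DataFrame:
    """Flatten reports to one row per station (the CSV layout of the CLI)."""
    rows = []
    for station, rep in reports.items():
        row = {
            "station": station,
            "jja_p95_hismax24_f": rep.threshold_f,
            "exact_match_fraction": rep.direct.exact_fraction,
            "n_heat_season_days": rep.direct.n_days,
            "n24_extreme_days": rep.underestimation.n24_extreme_days,
            "nest_extreme_days": rep.underestimation.nest_extreme_days,
            "underestimation_ratio": rep.underestimation.ratio,
        }
        for label in DIFF_BIN_LABELS:
            row[f"diff_bin_{label}"] = rep.direct.bin_fractions[label]
        for c in (1, 2, 3):
            row[f"case{c}_fraction"] = rep.case_fractions[c]
        for name in NWS_CATEGORIES:
            key = name.lower().replace(" ", "_")
            row[f"n_{key}_his24"] = rep.category_counts_his24.get(name, 0)
            row[f"n_{key}_hisest"] = rep.category_counts_hisest.get(name, 0)
        rows.append(row)
    return pd.DataFrame(rows)
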