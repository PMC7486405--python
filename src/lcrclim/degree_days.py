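"""Degree-day exposure construction from daily temperature extremes.

Daily degree days above a threshold are computed with the single-sine
method: the diurnal temperature course is idealized as one sine wave with
mean ``M = (tmax + tmin) / 2`` and amplitude ``W = (tmax - tmin) / 2``, and
the degree days for the day are the time-average exceedance of the curve
over the threshold.  Season exposures sum the daily values over a fixed
calendar window (April-September by default) at a schedule of integer
thresholds, so that piecewise-linear exposure bins at any candidate knot
pair can be assembled afterwards without touching the daily data again.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Integer thresholds precomputed by default: the fixed lower cutoff at
#: 10 degC plus every candidate knot between 20 and 43 degC.
DEFAULT_THRESHOLDS: tuple[int, ...] = (10,) + tuple(range(20, 44))

#: April 1 through September 30, inclusive.
DEFAULT_SEASON: tuple[str, str] = ("04-01", "09-30")

WEATHER_COLUMNS = ["county_id", "state_id", "date", "tmin_c", "tmax_c", "prec_mm"]


@dataclass(frozen=True)
class PiecewiseSpec:
    """Knot locations of the piecewise-linear temperature response.

    The lower cutoff is fixed at 10 degC; the two free knots are
    constrained to the search windows [20, 35] and [36, 43] degC.
    """

    c1: float
    c2: float
    c0: float = field(default=10.0)

    def __post_init__(self) -> None:
        if not (self.c0 < self.c1 < self.c2):
            raise ValueError(f"knots must satisfy c0 < c1 < c2, got {self}")
        if not (20 <= self.c1 <= 35):
            raise ValueError(f"c1 must lie in [20, 35] degC, got {self.c1}")
        if not (36 <= self.c2 <= 43):
            raise ValueError(f"c2 must lie in [36, 43] degC, got {self.c2}")


def daily_dd(tmin, tmax, threshold):
    """Single-sine degree days above ``threshold`` for one day.

    Parameters are in degC; accepts scalars or broadcastable arrays.
    With ``M = (tmax+tmin)/2`` and ``W = (tmax-tmin)/2`` the value is

    * ``0`` when ``tmax <= threshold``,
    * ``M - threshold`` when ``tmin >= threshold`` (curve entirely above),
    * otherwise ``[(M - threshold)(pi/2 - theta) + W cos(theta)] / pi``
      with ``theta = arcsin((threshold - M) / W)``.

    Returns degree days in degC*day, in ``[0, max(0, M - threshold) + W]``.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    thr = np.asarray(threshold, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin encountered")
    tmin, tmax, thr = np.broadcast_arrays(tmin, tmax, thr)

    m = 0.5 * (tmax + tmin)
    w = 0.5 * (tmax - tmin)
    out = np.zeros(m.shape)

    above = tmin >= thr
    out[above] = (m - thr)[above]

    partial = (tmax > thr) & ~above
    if np.any(partial):
        mp = m[partial]
        wp = w[partial]  # > 0 here, since tmax > thr > tmin
        tp = thr[partial]
        theta = np.arcsin((tp - mp) / wp)
        out[partial] = ((mp - tp) * (np.pi / 2 - theta) + wp * np.cos(theta)) / np.pi

    if out.ndim == 0:
        return float(out)
    return out


def read_weather(path) -> pd.DataFrame:
    """Read a daily weather CSV (county_id, state_id, date, tmin_c, tmax_c, prec_mm)."""
    df = pd.read_csv(path, parse_dates=["date"])
    missing = set(WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weather file missing columns: {sorted(missing)}")
    return df


def shift_weather(weather: pd.DataFrame, delta: float) -> pd.DataFrame:
    """Uniform warming scenario: add ``delta`` degC to tmin and tmax.

    Precipitation and all other columns are unchanged.
    """
    out = weather.copy()
    out["tmin_c"] = out["tmin_c"] + delta
    out["tmax_c"] = out["tmax_c"] + delta
    return out


def _season_mask(dates: pd.Series, season: tuple[str, str]) -> np.ndarray:
    start_m, start_d = (int(x) for x in season[0].split("-"))
    end_m, end_d = (int(x) for x in season[1].split("-"))
    if (start_m, start_d) >= (end_m, end_d):
        raise ValueError(f"season start must precede end, got {season}")
    md = dates.dt.month * 100 + dates.dt.day
    return ((md >= start_m * 100 + start_d) & (md <= end_m * 100 + end_d)).to_numpy()


def _season_length(year: int, season: tuple[str, str]) -> int:
    start = pd.Timestamp(f"{year}-{season[0]}")
    end = pd.Timestamp(f"{year}-{season[1]}")
    return int((end - start).days) + 1


def season_exposure(
    weather: pd.DataFrame,
    season: tuple[str, str] = DEFAULT_SEASON,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Aggregate daily weather to county-year growing-season exposures.

    Returns one row per county-year with columns ``dd_<T>`` (season total
    degree days above each threshold T), ``prec_total`` (season total
    precipitation, mm) and, when present in the input, the state id.
    County-years with an incomplete season record are excluded with a
    log message rather than imputed.
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted strictly ascending")

    mask = _season_mask(weather["date"], season)
    ws = weather.loc[mask]
    years = ws["date"].dt.year.to_numpy()
    county = ws["county_id"].to_numpy()

    keys = pd.MultiIndex.from_arrays([county, years], names=["county_id", "year"])
    codes, uniques = pd.factorize(keys, sort=True)
    n_groups = len(uniques)

    tmin = ws["tmin_c"].to_numpy(dtype=float)
    tmax = ws["tmax_c"].to_numpy(dtype=float)
    prec = ws["prec_mm"].to_numpy(dtype=float)
    if np.any(prec < 0):
        raise ValueError("negative precipitation encountered")

    data: dict[str, np.ndarray] = {}
    for thr in thresholds:
        dd = daily_dd(tmin, tmax, thr)
        data[f"dd_{thr:g}"] = np.bincount(codes, weights=dd, minlength=n_groups)
    data["prec_total"] = np.bincount(codes, weights=prec, minlength=n_groups)
    data["n_days"] = np.bincount(codes, minlength=n_groups)

    out = pd.DataFrame({"county_id": uniques.get_level_values(0),
                        "year": uniques.get_level_values(1), **data})

    expected = out["year"].map(lambda y: _season_length(int(y), season))
    complete = out["n_days"] == expected
    if not complete.all():
        dropped = out.loc[~complete, ["county_id", "year"]]
        logger.warning(
            "excluding %d county-year(s) with incomplete season coverage: %s",
            len(dropped),
            dropped.to_records(index=False)[:10],
        )
        out = out.loc[complete]
    out = out.drop(columns="n_days")

    if "state_id" in weather.columns:
        states = weather.drop_duplicates("county_id").set_index("county_id")["state_id"]
        out.insert(1, "state_id", out["county_id"].map(states))
    return out.reset_index(drop=True)


def bin_exposures(exposure: pd.DataFrame, spec: PiecewiseSpec) -> pd.DataFrame:
    """Bin season degree days into the three piecewise-linear intervals.

    x1 = dd(10) - dd(c1), x2 = dd(c1) - dd(c2), x3 = dd(c2); the three
    components are non-negative and sum exactly to dd(10).
    """
    cols = [f"dd_{t:g}" for t in (spec.c0, spec.c1, spec.c2)]
    for c in cols:
        if c not in exposure.columns:
            raise KeyError(f"exposure table lacks required threshold column {c!r}")
    out = exposure.copy()
    d0, d1, d2 = (exposure[c].to_numpy(dtype=float) for c in cols)
    out["x1"] = d0 - d1
    out["x2"] = d1 - d2
    out["x3"] = d2
    return out
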