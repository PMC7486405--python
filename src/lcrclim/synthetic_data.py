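"""Synthetic county-year weather and crop-insurance records with known truth.

The generator emulates the schemas of the Cause-of-Loss (COL, indemnities
by cause) and Summary-of-Business (SOB, liabilities) insurance files and a
PRISM-style daily weather table, on an unbalanced county-year panel.  The
loss process is the estimation model itself: the latent loss-cost ratio is
piecewise linear in degree-day exposure with known knots and slopes,
quadratic in season precipitation, plus county effects, year effects, and
i.i.d. noise, truncated into [0, 1].  Total losses are allocated across
causes (drought, heat, excess moisture, cold, other) by softmax weights
that load monotonically on the corresponding weather features, so cause
losses always sum exactly to the total.

Because the generating model and the estimation model coincide wherever
truncation is inactive, downstream parameter- and impact-recovery tests
have an exact ground truth, returned as a :class:`TruthRecord`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .degree_days import PiecewiseSpec, bin_exposures, season_exposure, shift_weather

logger = logging.getLogger(__name__)

CANONICAL_CAUSES = ("drought", "heat", "excess_moisture", "cold", "other")

#: Raw cause-name spellings written into the COL file, per canonical cause.
#: Cold is deliberately split across its three raw spellings so readers must
#: re-aggregate them.
RAW_CAUSE_NAMES = {
    "drought": ["Drought"],
    "heat": ["Heat"],
    "excess_moisture": ["Excess Moisture/Precipitation/Rain"],
    "cold": ["Freeze", "Frost", "Cold Wet Weather"],
    "other": ["Other (Snow, Lightning, Etc.)"],
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic weather and loss process.

    Defaults are calibrated so season degree days above 29 degC average in
    the mid-50s (degC day) and season precipitation averages near 610 mm,
    the scale of eastern-US corn counties, with a mean loss-cost ratio
    near 0.12 and fewer than 1% of latent draws truncated.
    """

    n_states: int = 5
    counties_per_state: int = 8
    years: tuple[int, int] = (1989, 2014)
    season: tuple[str, str] = ("04-01", "09-30")
    crop: str = "CORN"

    # loss process
    true_knots: tuple[float, float] = (29.0, 38.0)
    true_beta: tuple[float, float, float] = (-6e-5, 1.0e-3, 8e-3)
    true_gamma: tuple[float, float] = (-4.0e-4, 3.3e-7)
    base_lcr: float = 0.14
    county_effect_sd: float = 0.015
    year_effect_sd: float = 0.02
    noise_sd: float = 0.03
    zero_inflation_prob: float = 0.0

    # weather process
    tmean_base: float = 13.0
    seasonal_amplitude: float = 12.5
    seasonal_peak_doy: int = 200
    diurnal_range: float = 11.0
    ar1_rho: float = 0.7
    temp_noise_sd: float = 2.0
    county_temp_sd: float = 1.0
    state_temp_span: float = 5.0
    rain_prob: float = 0.30
    rain_shape: float = 0.6
    rain_scale: float = 18.6

    # insurance book
    liability_mean: float = 2.0e6
    liability_log_sd: float = 0.5
    dropout_rate: float = 0.03

    # cause allocation (softmax over standardized weather features)
    alloc_base_shares: tuple[float, ...] = (0.45, 0.05, 0.20, 0.05, 0.25)
    alloc_sensitivity: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    alloc_noise_sd: float = 0.3
    cold_tmin_threshold: float = 5.0

    truth_delta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        c1, c2 = self.true_knots
        if not c1 < c2:
            raise ValueError("true_knots must satisfy c1 < c2")
        if self.n_states <= 0 or self.counties_per_state <= 0:
            raise ValueError("state and county counts must be positive")
        if self.years[0] > self.years[1]:
            raise ValueError("years range is empty")
        for name in ("county_effect_sd", "year_effect_sd", "noise_sd",
                     "temp_noise_sd", "county_temp_sd", "alloc_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        s, e = self.season
        if tuple(int(x) for x in s.split("-")) >= tuple(int(x) for x in e.split("-")):
            raise ValueError("season start must precede season end")

    @property
    def knot_spec(self) -> PiecewiseSpec:
        return PiecewiseSpec(c1=self.true_knots[0], c2=self.true_knots[1])

    @property
    def county_ids(self) -> list[str]:
        return [f"S{s:02d}C{c:03d}"
                for s in range(self.n_states)
                for c in range(self.counties_per_state)]

    @property
    def state_of_county(self) -> dict[str, str]:
        return {cid: cid[:3] for cid in self.county_ids}


@dataclass
class TruthRecord:
    """Ground truth of one synthetic draw, for recovery tests.

    ``county_impacts`` holds each county's analytic warming impact for a
    uniform ``delta`` degC shift: beta dotted with the county's change in
    time-averaged exposure bins, which is exactly linear in ``beta``.
    ``panel`` carries the realized (truncated) and latent total LCR per
    county-year so readers can be checked against the generator.
    """

    beta: np.ndarray
    gamma: np.ndarray
    knots: PiecewiseSpec
    delta: float
    county_impacts: pd.DataFrame
    avg_impact: float
    panel: pd.DataFrame
    clamp_fraction: float
    county_effects: pd.Series | None = None
    year_effects: pd.Series | None = None


def _streams(config: GeneratorConfig) -> dict[str, np.random.Generator]:
    names = ["weather", "effects", "allocation", "liability", "dropout"]
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def seasonal_tmean(config: GeneratorConfig, day_of_year) -> np.ndarray:
    """Deterministic seasonal mean-temperature curve (no county offset)."""
    doy = np.asarray(day_of_year, dtype=float)
    return config.tmean_base + config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.seasonal_peak_doy) / 365.25
    )


def county_temperature_offsets(config: GeneratorConfig,
                               rng: np.random.Generator) -> np.ndarray:
    """Per-county mean-temperature offsets: a linear cross-state gradient
    (warm to cool) plus i.i.d. county noise."""
    if config.n_states > 1:
        state_offsets = np.linspace(config.state_temp_span / 2,
                                    -config.state_temp_span / 2,
                                    config.n_states)
    else:
        state_offsets = np.zeros(1)
    per_state = np.repeat(state_offsets, config.counties_per_state)
    noise = rng.normal(0.0, config.county_temp_sd, size=per_state.size)
    return per_state + noise


def generate_weather(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate the daily weather table for every county and calendar day.

    Temperature is a county-specific seasonal sine plus an AR(1) daily
    anomaly; tmax/tmin straddle the daily mean by half the diurnal range.
    Precipitation is an independent Bernoulli-gamma draw per day.
    """
    rng = _streams(config)["weather"]
    counties = np.array(config.county_ids)
    n_c = counties.size

    dates = pd.date_range(f"{config.years[0]}-01-01", f"{config.years[1]}-12-31",
                          freq="D")
    n_d = dates.size
    doy = dates.dayofyear.to_numpy()

    offsets = county_temperature_offsets(config, rng)
    base = seasonal_tmean(config, doy)[None, :] + offsets[:, None]

    innov = rng.normal(0.0, config.temp_noise_sd, size=(n_c, n_d))
    if config.ar1_rho != 0.0:
        anom = signal.lfilter([1.0], [1.0, -config.ar1_rho], innov, axis=1)
    else:
        anom = innov
    tmean = base + anom
    half = config.diurnal_range / 2.0

    wet = rng.random(size=(n_c, n_d)) < config.rain_prob
    amounts = rng.gamma(config.rain_shape, config.rain_scale, size=(n_c, n_d))
    prec = np.where(wet, amounts, 0.0)

    return pd.DataFrame({
        "county_id": np.repeat(counties, n_d),
        "state_id": np.repeat([config.state_of_county[c] for c in counties], n_d),
        "date": np.tile(dates.to_numpy(), n_c),
        "tmin_c": (tmean - half).ravel(),
        "tmax_c": (tmean + half).ravel(),
        "prec_mm": prec.ravel(),
    })


def _cool_days(weather: pd.DataFrame, config: GeneratorConfig,
               keys: pd.DataFrame) -> np.ndarray:
    """Season days with tmin below the cold threshold, per county-year."""
    from .degree_days import _season_mask

    mask = _season_mask(weather["date"], config.season)
    ws = weather.loc[mask]
    cool = (ws["tmin_c"] < config.cold_tmin_threshold).astype(float)
    counts = cool.groupby([ws["county_id"].to_numpy(),
                           ws["date"].dt.year.to_numpy()]).sum()
    idx = pd.MultiIndex.from_frame(keys[["county_id", "year"]])
    return counts.reindex(idx).fillna(0.0).to_numpy()


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_losses(
    weather: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Draw COL-style loss records and SOB-style liabilities from weather.

    Returns ``(losses, liabilities, truth)``.  Losses carry raw cause-name
    spellings; liabilities are lognormal around ``liability_mean`` and
    constant within county; ``truth`` records the latent process and the
    analytic per-county warming impact for ``config.truth_delta``.
    """
    streams = _streams(config)
    spec = config.knot_spec
    thresholds = sorted({10.0, spec.c1, spec.c2})

    expo = season_exposure(weather, config.season, thresholds)
    expo = bin_exposures(expo, spec)
    missing = set(config.county_ids) - set(expo["county_id"])
    if missing:
        raise ValueError(f"weather does not cover counties: {sorted(missing)[:5]}")

    x = expo[["x1", "x2", "x3"]].to_numpy()
    prec = expo["prec_total"].to_numpy()
    beta = np.asarray(config.true_beta, dtype=float)
    gamma = np.asarray(config.true_gamma, dtype=float)

    # Center weather terms at their sample means so base_lcr is the mean
    # latent level; centering shifts only the intercept, never the slopes.
    wterm = (x - x.mean(axis=0)) @ beta
    pterm = gamma[0] * (prec - prec.mean()) + gamma[1] * (prec**2 - (prec**2).mean())

    rng_eff = streams["effects"]
    counties = np.array(config.county_ids)
    years = np.arange(config.years[0], config.years[1] + 1)
    c_eff = pd.Series(rng_eff.normal(0, config.county_effect_sd, counties.size),
                      index=counties)
    u_eff = pd.Series(rng_eff.normal(0, config.year_effect_sd, years.size),
                      index=years)
    eps = rng_eff.normal(0, config.noise_sd, len(expo))

    latent = (config.base_lcr + wterm + pterm
              + c_eff.reindex(expo["county_id"]).to_numpy()
              + u_eff.reindex(expo["year"]).to_numpy()
              + eps)
    if config.zero_inflation_prob > 0:
        zero = rng_eff.random(len(expo)) < config.zero_inflation_prob
        latent = np.where(zero, 0.0, latent)
    lcr = np.clip(latent, 0.0, 1.0)
    clamp_fraction = float(np.mean((latent < 0) | (latent > 1)))
    if clamp_fraction > 0.01:
        logger.warning("%.1f%% of latent LCR draws truncated into [0, 1]",
                       100 * clamp_fraction)

    # liabilities: constant within county across years
    rng_liab = streams["liability"]
    mu = np.log(config.liability_mean) - config.liability_log_sd**2 / 2
    liab_by_county = pd.Series(
        np.exp(rng_liab.normal(mu, config.liability_log_sd, counties.size)),
        index=counties)
    liability = liab_by_county.reindex(expo["county_id"]).to_numpy()
    total_loss = lcr * liability

    # softmax cause allocation over standardized weather features
    rng_alloc = streams["allocation"]
    feats = np.column_stack([
        _zscore(expo[f"dd_{spec.c1:g}"].to_numpy()),        # drought
        _zscore(expo[f"dd_{spec.c2:g}"].to_numpy()),        # heat
        _zscore(prec),                                      # excess moisture
        _zscore(_cool_days(weather, config, expo)),         # cold
    ])
    sens = np.asarray(config.alloc_sensitivity, dtype=float)
    logits = np.log(np.asarray(config.alloc_base_shares, dtype=float))[None, :].repeat(
        len(expo), axis=0)
    logits[:, :4] += feats * sens[None, :]
    logits += rng_alloc.normal(0, config.alloc_noise_sd, logits.shape)
    shares = np.exp(logits - logits.max(axis=1, keepdims=True))
    shares /= shares.sum(axis=1, keepdims=True)

    cause_loss = shares * total_loss[:, None]
    # enforce exact conservation against float round-off
    cause_loss[:, -1] = total_loss - cause_loss[:, :-1].sum(axis=1)

    state = expo["state_id"].to_numpy()
    year = expo["year"].to_numpy()
    county = expo["county_id"].to_numpy()

    # unbalanced panel: some county-years never enter the insurance book
    rng_drop = streams["dropout"]
    keep = rng_drop.random(len(expo)) >= config.dropout_rate

    loss_rows = []
    for j, cause in enumerate(CANONICAL_CAUSES):
        names = RAW_CAUSE_NAMES[cause]
        amounts = cause_loss[:, j]
        pos = keep & (amounts > 0)
        # split evenly across this cause's raw spellings, exactly conserving
        part = amounts[pos] / len(names)
        for k, raw in enumerate(names):
            amt = part if k < len(names) - 1 else amounts[pos] - part * (len(names) - 1)
            loss_rows.append(pd.DataFrame({
                "year": year[pos], "state_id": state[pos],
                "county_id": county[pos], "crop": config.crop,
                "cause": raw, "indemnity_usd": amt,
            }))
    losses = (pd.concat(loss_rows, ignore_index=True)
              .sort_values(["year", "county_id", "cause"], kind="stable")
              .reset_index(drop=True))

    liabilities = pd.DataFrame({
        "year": year[keep], "state_id": state[keep], "county_id": county[keep],
        "crop": config.crop, "liability_usd": liability[keep],
    }).sort_values(["year", "county_id"], kind="stable").reset_index(drop=True)

    truth = TruthRecord(
        beta=beta, gamma=gamma, knots=spec, delta=config.truth_delta,
        county_impacts=analytic_warming_impact(weather, config),
        avg_impact=np.nan,
        panel=pd.DataFrame({"county_id": county, "year": year,
                            "latent_lcr": latent, "lcr_total": lcr,
                            "in_book": keep}),
        clamp_fraction=clamp_fraction,
        county_effects=c_eff,
        year_effects=u_eff,
    )
    truth.avg_impact = float(truth.county_impacts["impact"].mean())
    return losses, liabilities, truth


def analytic_warming_impact(weather: pd.DataFrame,
                            config: GeneratorConfig) -> pd.DataFrame:
    """Exact per-county warming impact implied by the generator's response.

    For each county, the change in the time-averaged exposure-bin vector
    under a uniform ``truth_delta`` shift, dotted with ``true_beta``.
    """
    spec = config.knot_spec
    thresholds = sorted({10.0, spec.c1, spec.c2})
    beta = np.asarray(config.true_beta, dtype=float)

    def county_means(w):
        e = bin_exposures(season_exposure(w, config.season, thresholds), spec)
        return e.groupby("county_id")[["x1", "x2", "x3"]].mean()

    base = county_means(weather)
    warmed = county_means(shift_weather(weather, config.truth_delta))
    shift = warmed - base
    return pd.DataFrame({"county_id": base.index,
                         "impact": shift.to_numpy() @ beta}).reset_index(drop=True)


def write_fixture(weather: pd.DataFrame, losses: pd.DataFrame,
                  liabilities: pd.DataFrame, path) -> dict[str, Path]:
    """Write weather.csv, col.csv and sob.csv under ``path``.

    The CSVs round-trip losslessly through :func:`lcrclim.degree_days.read_weather`,
    :func:`lcrclim.loss_cost.read_col` and :func:`lcrclim.loss_cost.read_sob`.
    """
    for name, df in (("weather", weather), ("losses", losses),
                     ("liabilities", liabilities)):
        if len(df) == 0:
            raise ValueError(f"refusing to write empty {name} table")
    if (losses["cause"].astype(str).str.strip() == "").any():
        raise ValueError("loss records with empty cause names")

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = {}

    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"]).dt.strftime("%Y-%m-%d")
    out["weather"] = path / "weather.csv"
    w.to_csv(out["weather"], index=False,
             columns=["county_id", "state_id", "date", "tmin_c", "tmax_c", "prec_mm"])

    out["col"] = path / "col.csv"
    losses.to_csv(out["col"], index=False,
                  columns=["year", "state_id", "county_id", "crop", "cause",
                           "indemnity_usd"])
    out["sob"] = path / "sob.csv"
    liabilities.to_csv(out["sob"], index=False,
                       columns=["year", "state_id", "county_id", "crop",
                                "liability_usd"])
    return out


def simulate(config: GeneratorConfig):
    """Convenience wrapper: weather, losses, liabilities, truth in one call."""
    weather = generate_weather(config)
    losses, liabilities, truth = generate_losses(weather, config)
    return weather, losses, liabilities, truth
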