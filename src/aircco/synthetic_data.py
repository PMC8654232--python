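"""Synthetic exposure fields and ED-visit events with known ground truth.

The generator emulates the study conditions of a statewide pediatric-asthma
case-crossover analysis: ~1,079 census tracts, a 10-year daily series
(2005–2014), six criteria pollutants plus temperature and dewpoint with
seasonal cycles, day-to-day autocorrelation and tract-level spatial
gradients, and ED-visit events drawn from the same logit structure the
downstream hierarchical model assumes.  Because the true per-unit log-odds
(``true_betas``) are inputs, every downstream stage — referent selection,
covariate assembly, MCMC — is testable by parameter recovery without any
real data.

Visit counts are drawn as a thinned Poisson process per tract-day whose log
intensity equals the model's linear predictor.  A per-child Bernoulli scheme
would need a population register; conditioning on cases only, the Poisson
scheme induces the identical retrospective case-crossover likelihood.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exposure import TractSeries, rolling_3dma
from .seasons import SEASONS, day_of_year_365, season_doy_range

__all__ = [
    "SeriesParams",
    "WeatherParams",
    "SimConfig",
    "default_pollutant_params",
    "default_baseline_by_doy",
    "generate_exposures",
    "generate_visits",
]

#: day-of-year of the default back-to-school surge centre (Aug 24)
SURGE_DOY = 236


@dataclass(frozen=True)
class SeriesParams:
    """Generator parameters for one daily series, in the variable's native units.

    ``mean`` is the annual mean; ``amplitude`` the half-range of the seasonal
    sinusoid peaking at ``peak_doy``; ``rho`` the lag-1 autocorrelation of the
    AR(1) deviation with stationary standard deviation ``sd``; ``spatial_sd``
    scales a fixed west–east tract offset gradient.
    """

    mean: float
    amplitude: float = 0.0
    rho: float = 0.0
    sd: float = 0.0
    spatial_sd: float = 0.0
    peak_doy: int = 197

    def __post_init__(self):
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("autocorrelation must be in [0, 1)")
        if self.sd < 0 or self.spatial_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class WeatherParams:
    temperature: SeriesParams
    dewpoint: SeriesParams
    correlation: float = 0.85  # of daily anomalies

    def __post_init__(self):
        if not (-1.0 <= self.correlation <= 1.0):
            raise ValueError("weather correlation must be in [-1, 1]")


def default_pollutant_params() -> dict[str, SeriesParams]:
    """Southeast-US-like pollutant parameters (native units).

    Chosen so that 3-day-moving-average interquartile ranges land near the
    magnitudes a low-air-pollution southeastern state exhibits
    (NOx ~15 ppb, O3 ~0.017 ppm, SO2 ~4 ppb, PM ~4.5 ug/m3).
    Combustion pollutants peak in winter, O3 and fine PM in summer.
    """
    return {
        "NOx": SeriesParams(12.0, 6.0, 0.70, 6.0, 2.5, peak_doy=15),
        "O3": SeriesParams(0.040, 0.010, 0.75, 0.006, 0.002, peak_doy=180),
        "SO2": SeriesParams(4.0, 1.5, 0.60, 1.5, 0.8, peak_doy=15),
        # CO is regenerated as a near-affine function of NOx (shared
        # combustion source); these params set only its residual noise.
        "CO": SeriesParams(0.05, 0.0, 0.30, 0.01, 0.0, peak_doy=15),
        "PM2.5": SeriesParams(10.5, 2.5, 0.65, 2.2, 1.0, peak_doy=197),
        "PM10-2.5": SeriesParams(6.0, 1.8, 0.55, 2.0, 1.0, peak_doy=140),
    }


def default_weather_params() -> WeatherParams:
    return WeatherParams(
        temperature=SeriesParams(17.5, 8.5, 0.80, 3.0, 1.0, peak_doy=197),
        dewpoint=SeriesParams(11.0, 8.0, 0.80, 3.0, 1.0, peak_doy=197),
        correlation=0.85,
    )


def default_baseline_by_doy(surge_height: float = 0.8, surge_width: float = 12.0,
                            surge_doy: int = SURGE_DOY) -> np.ndarray:
    """Log-relative daily visit intensity over a 365-day year.

    Piecewise-constant seasonal burden levels (log of each asthma season's
    mean daily visits relative to the annual mean, matching the observed
    medium/medium-high/low/high ordering) plus a smooth Gaussian
    back-to-school bump centred on late August.
    """
    season_level = {
        "winter": np.log(16.5 / 18.1),
        "spring": np.log(18.9 / 18.1),
        "summer": np.log(9.4 / 18.1),
        "fall": np.log(23.5 / 18.1),
    }
    base = np.empty(365)
    for name in SEASONS:
        first, last = season_doy_range(name)
        base[first - 1:last] = season_level[name]
    doy = np.arange(1, 366)
    bump = surge_height * np.exp(-0.5 * ((doy - surge_doy) / surge_width) ** 2)
    return base + bump


@dataclass
class SimConfig:
    """Study-scale defaults: 1,079 tracts, 2005–2014, ~18 visits/day statewide."""

    n_tracts: int = 1079
    start_date: dt.date = dt.date(2005, 1, 1)
    end_date: dt.date = dt.date(2014, 12, 31)
    pollutant_params: dict[str, SeriesParams] = field(
        default_factory=default_pollutant_params
    )
    weather_params: WeatherParams = field(default_factory=default_weather_params)
    true_betas: dict[str, float] = field(default_factory=dict)
    baseline_logit_by_doy: np.ndarray = field(
        default_factory=default_baseline_by_doy
    )
    target_daily_visits: float = 18.1
    stratum_sd: float = 0.10  # sd of year-month-day-of-week effects
    co_per_nox: float = 0.02  # ppm CO per ppb NOx (shared combustion driver)
    seed: int = 0

    def __post_init__(self):
        if self.n_tracts < 1:
            raise ValueError("n_tracts must be >= 1")
        if self.end_date < self.start_date:
            raise ValueError(
                f"invalid date range: end {self.end_date} before start {self.start_date}"
            )
        self.baseline_logit_by_doy = np.asarray(
            self.baseline_logit_by_doy, dtype=float
        )
        if self.baseline_logit_by_doy.shape != (365,):
            raise ValueError("baseline_logit_by_doy must have 365 entries")


def _ar1(rng, n_series: int, n_days: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) deviations with marginal sd ``sd`` and lag-1 corr ``rho``."""
    if sd == 0.0:
        return np.zeros((n_series, n_days))
    z = rng.standard_normal((n_series, n_days))
    if rho == 0.0:
        return sd * z
    innov = z * sd * np.sqrt(1.0 - rho**2)
    innov[:, 0] = z[:, 0] * sd  # stationary start
    return lfilter([1.0], [1.0, -rho], innov, axis=1)


def _gradient(centroids: np.ndarray, spatial_sd: float) -> np.ndarray:
    """Standardized west–east offset per tract."""
    x = centroids[:, 0]
    if len(x) < 2 or np.ptp(x) == 0 or spatial_sd == 0:
        return np.zeros(len(x))
    g = (x - x.mean()) / x.std()
    return spatial_sd * g


def generate_exposures(config: SimConfig) -> TractSeries:
    """Generate per-tract daily pollutant and weather series.

    Each series is a seasonal sinusoid plus an AR(1) deviation plus a fixed
    tract offset.  Pollutants are truncated at 0; PM10 is constructed as
    PM2.5 plus the (nonnegative) coarse fraction, so PM10 >= PM2.5 holds
    everywhere by construction; CO is an affine function of NOx plus small
    noise, reproducing their shared combustion source and the resulting
    collinearity.
    """
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(config.start_date, config.end_date, freq="D")
    n_days = len(dates)
    n_t = config.n_tracts
    centroids = rng.uniform(0.0, 300.0, size=(n_t, 2))  # planar, km-scale
    doy = np.array([day_of_year_365(d) for d in dates])

    def seasonal(p: SeriesParams) -> np.ndarray:
        return p.amplitude * np.cos(2 * np.pi * (doy - p.peak_doy) / 365.0)

    series: dict[str, np.ndarray] = {}
    for name in ("NOx", "O3", "SO2", "PM2.5", "PM10-2.5"):
        p = config.pollutant_params[name]
        vals = (
            p.mean
            + seasonal(p)[None, :]
            + _gradient(centroids, p.spatial_sd)[:, None]
            + _ar1(rng, n_t, n_days, p.rho, p.sd)
        )
        series[name] = np.clip(vals, 0.0, None)

    pco = config.pollutant_params["CO"]
    co = (
        pco.mean
        + config.co_per_nox * series["NOx"]
        + _ar1(rng, n_t, n_days, pco.rho, pco.sd)
    )
    series["CO"] = np.clip(co, 0.0, None)
    series["PM10"] = series["PM2.5"] + series["PM10-2.5"]

    wp = config.weather_params
    a_t = _ar1(rng, n_t, n_days, wp.temperature.rho, 1.0) if wp.temperature.sd else 0.0
    a_d = _ar1(rng, n_t, n_days, wp.dewpoint.rho, 1.0) if wp.dewpoint.sd else 0.0
    rho_w = wp.correlation
    series["temperature"] = (
        wp.temperature.mean
        + seasonal(wp.temperature)[None, :]
        + _gradient(centroids, wp.temperature.spatial_sd)[:, None]
        + wp.temperature.sd * np.asarray(a_t)
    ) * np.ones((n_t, n_days))
    series["dewpoint"] = (
        wp.dewpoint.mean
        + seasonal(wp.dewpoint)[None, :]
        + _gradient(centroids, wp.dewpoint.spatial_sd)[:, None]
        + wp.dewpoint.sd
        * (rho_w * np.asarray(a_t) + np.sqrt(max(0.0, 1 - rho_w**2)) * np.asarray(a_d))
    ) * np.ones((n_t, n_days))

    variables = [
        "NOx", "O3", "SO2", "CO", "PM2.5", "PM10", "PM10-2.5",
        "temperature", "dewpoint",
    ]
    values = np.stack([series[v] for v in variables], axis=2)
    tract_ids = [f"T{i:04d}" for i in range(n_t)]
    return TractSeries(tract_ids, centroids, dates, variables, values,
                       attrs={"seed": config.seed})


#: marginal frequencies used for pass-through demographic labels
_STRATA_MARGINALS = {
    "sex": (["Male", "Female"], [0.585, 0.415]),
    "age_group": (["5-9", "10-14", "15-19"], [0.469, 0.288, 0.243]),
    "race": (["White", "African American", "Other"], [0.267, 0.680, 0.053]),
    "payor": (["Public", "Private", "Other"], [0.583, 0.255, 0.162]),
    "region": (["Upstate", "Midlands", "Lowcountry"], [0.207, 0.524, 0.269]),
}


def generate_visits(exposures: TractSeries, config: SimConfig) -> pd.DataFrame:
    """Draw ED-visit events from the case-crossover model's own logit structure.

    Per tract-day, the log visit intensity is the day-of-year baseline plus a
    year-month-day-of-week stratum effect plus ``sum(true_beta * 3DMA)`` over
    the configured covariates; the intensity is normalized so the expected
    total equals ``target_daily_visits`` per day, then a Poisson count is
    drawn and expanded to one row per visit with pass-through demographic
    labels.  Days whose 3-day moving average is undefined (the first two
    study days) generate no visits.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    dates = exposures.dates
    n_t = len(exposures.tract_ids)
    n_d = len(dates)

    doy = np.array([day_of_year_365(d) for d in dates])
    linpred = np.tile(config.baseline_logit_by_doy[doy - 1], (n_t, 1))

    if config.stratum_sd > 0:
        keys = [(d.year, d.month, d.weekday()) for d in dates]
        uniq = sorted(set(keys))
        effects = rng.normal(0.0, config.stratum_sd, size=len(uniq))
        lookup = dict(zip(uniq, effects))
        linpred += np.array([lookup[k] for k in keys])[None, :]

    for name, beta in config.true_betas.items():
        if name not in exposures.variables:
            raise KeyError(f"true_betas names unknown variable {name!r}")
        linpred = linpred + beta * rolling_3dma(exposures.var(name))

    valid = np.all(np.isfinite(linpred), axis=0)
    lam = np.where(valid[None, :], np.exp(np.nan_to_num(linpred)), 0.0)
    expected_total = config.target_daily_visits * n_d
    if expected_total <= 0 or lam.sum() == 0:
        warnings.warn("requested expected total of 0 visits; returning empty table")
        return _empty_visits()
    lam *= expected_total / lam.sum()
    counts = rng.poisson(lam)

    t_idx, d_idx = np.nonzero(counts)
    reps = counts[t_idx, d_idx]
    tract_col = np.repeat(np.asarray(exposures.tract_ids)[t_idx], reps)
    date_col = np.repeat(dates.values[d_idx], reps)
    n_visits = int(reps.sum())
    out = pd.DataFrame(
        {
            "visit_id": [f"V{i:07d}" for i in range(n_visits)],
            "date": pd.DatetimeIndex(date_col),
            "tract_id": tract_col,
        }
    )
    order = np.argsort(out["date"].values, kind="stable")
    out = out.iloc[order].reset_index(drop=True)
    out["visit_id"] = [f"V{i:07d}" for i in range(n_visits)]
    for col, (labels, probs) in _STRATA_MARGINALS.items():
        out[col] = rng.choice(labels, size=n_visits, p=probs)
    out.attrs["total_visits"] = n_visits
    return out


def _empty_visits() -> pd.DataFrame:
    cols = ["visit_id", "date", "tract_id", *_STRATA_MARGINALS]
    df = pd.DataFrame({c: [] for c in cols})
    df.attrs["total_visits"] = 0
    return df


def write_visits_csv(visits: pd.DataFrame, path) -> None:
    out = visits.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_visits_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df
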