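"""Gridded exposure fields and tract-level daily series.

This module turns daily pollutant values on a regular grid (e.g. 12 km
chemical-transport-model output) into census-tract-level daily series via
inverse distance weighting, and provides the derived exposure quantities the
case-crossover design consumes: the coarse particulate fraction
(PM10-2.5 = PM10 - PM2.5), 3-day moving averages over lag days 0/1/2, and
season-stratified Spearman correlation matrices.

Missing values are carried as NaN throughout and are never silently zeroed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .seasons import day_of_year_365, season_doy_range

__all__ = [
    "GridField",
    "TractSeries",
    "idw_interpolate",
    "coarse_fraction",
    "add_coarse_fraction",
    "moving_average_3day",
    "rolling_3dma",
    "seasonal_spearman",
    "plot_correlation_heatmap",
]

#: weather variables are not truncated at zero; pollutants are
WEATHER_VARIABLES = ("temperature", "dewpoint")


@dataclass
class GridField:
    """Daily pollutant values on a set of planar grid points.

    Parameters
    ----------
    points
        ``(n_points, 2)`` planar coordinates; duplicates are rejected.
    dates
        Strictly increasing daily calendar index.
    pollutants
        Variable names, one per slice of the last axis of ``values``.
    values
        ``(n_points, n_days, n_pollutants)`` array; NaN marks missing.
    """

    points: np.ndarray
    dates: pd.DatetimeIndex
    pollutants: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n_points, 2)")
        if len(np.unique(self.points, axis=0)) != len(self.points):
            raise ValueError("duplicate grid coordinates")
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValueError("dates must be strictly increasing")
        expected = (len(self.points), len(self.dates), len(self.pollutants))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != expected {expected}"
            )
        if np.isinf(self.values).any():
            raise ValueError("non-finite (infinite) grid values; use NaN for missing")


@dataclass
class TractSeries:
    """Per-tract daily series of pollutants and weather.

    ``values`` is ``(n_tracts, n_days, n_variables)`` with NaN for missing.
    """

    tract_ids: list
    centroids: np.ndarray
    dates: pd.DatetimeIndex
    variables: list[str]
    values: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.tract_ids), len(self.dates), len(self.variables))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != expected {expected}"
            )
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValueError("dates must be strictly increasing")
        self._date_pos = {d: i for i, d in enumerate(self.dates.normalize())}
        self._tract_pos = {t: i for i, t in enumerate(self.tract_ids)}

    # -- indexing helpers -------------------------------------------------
    def var(self, name: str) -> np.ndarray:
        """``(n_tracts, n_days)`` view of one variable."""
        return self.values[:, :, self.variables.index(name)]

    def date_index(self, date) -> int:
        ts = pd.Timestamp(date).normalize()
        if ts not in self._date_pos:
            raise KeyError(f"date {date} outside series range")
        return self._date_pos[ts]

    def tract_index(self, tract_id) -> int:
        return self._tract_pos[tract_id]

    def add_variable(self, name: str, arr: np.ndarray) -> None:
        arr = np.asarray(arr, dtype=float)
        if arr.shape != self.values.shape[:2]:
            raise ValueError("array shape does not match (n_tracts, n_days)")
        self.values = np.concatenate([self.values, arr[:, :, None]], axis=2)
        self.variables = list(self.variables) + [name]

    def series(self, tract_id, variable: str) -> pd.Series:
        """One tract's daily series for one variable, indexed by date."""
        return pd.Series(
            self.var(variable)[self.tract_index(tract_id)], index=self.dates
        )

    # -- IO ---------------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        n_t, n_d, n_v = self.values.shape
        return pd.DataFrame(
            {
                "tract_id": np.repeat(self.tract_ids, n_d * n_v),
                "date": np.tile(np.repeat(self.dates.strftime("%Y-%m-%d"), n_v), n_t),
                "variable": np.tile(self.variables, n_t * n_d),
                "value": self.values.ravel(),
            }
        )

    def write_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_long(cls, df: pd.DataFrame, centroids=None) -> "TractSeries":
        tracts = sorted(df["tract_id"].unique().tolist())
        dates = pd.DatetimeIndex(sorted(pd.to_datetime(df["date"]).unique()))
        variables = sorted(df["variable"].unique().tolist())
        values = np.full((len(tracts), len(dates), len(variables)), np.nan)
        ti = pd.Index(tracts).get_indexer(df["tract_id"])
        di = dates.get_indexer(pd.to_datetime(df["date"]))
        vi = pd.Index(variables).get_indexer(df["variable"])
        values[ti, di, vi] = df["value"].to_numpy(dtype=float)
        if centroids is None:
            centroids = np.zeros((len(tracts), 2))
        return cls(tracts, centroids, dates, variables, values)

    @classmethod
    def read_csv(cls, path, centroids=None) -> "TractSeries":
        return cls.from_long(pd.read_csv(path), centroids=centroids)


def idw_interpolate(
    field: GridField,
    centroids: np.ndarray,
    power: float = 2.0,
    k: int = 4,
    tract_ids=None,
) -> TractSeries:
    """Inverse-distance-weighted interpolation of a grid field to centroids.

    For each centroid the ``k`` nearest grid points contribute with weights
    ``d**(-power)``; points with missing (NaN) values on a day are excluded
    from that day's weighted mean.  A centroid coinciding with a grid point
    returns that point's value exactly when it is present.  Days on which all
    ``k`` neighbours are missing yield NaN (flagged missing, never zero).
    """
    if power <= 0:
        raise ValueError("power must be > 0")
    centroids = np.asarray(centroids, dtype=float)
    if tract_ids is None:
        tract_ids = [f"T{i:04d}" for i in range(len(centroids))]
    k = int(min(k, len(field.points)))
    if k < 1:
        raise ValueError("need at least one grid point")
    tree = cKDTree(field.points)
    dist, idx = tree.query(centroids, k=k)
    dist = np.atleast_2d(dist).reshape(len(centroids), k)
    idx = np.atleast_2d(idx).reshape(len(centroids), k)

    exact = dist <= 1e-12
    with np.errstate(divide="ignore"):
        w = np.where(exact, 0.0, dist ** (-power))  # exact matches handled below

    n_t, n_d = len(centroids), len(field.dates)
    out = np.full((n_t, n_d, len(field.pollutants)), np.nan)
    for v in range(len(field.pollutants)):
        vals = field.values[:, :, v][idx]          # (n_tracts, k, n_days)
        finite = np.isfinite(vals)
        wt = w[:, :, None] * finite
        den = wt.sum(axis=1)
        num = np.where(finite, vals, 0.0)
        num = (num * w[:, :, None]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[:, :, v] = np.where(den > 0, num / den, np.nan)
        # zero-distance rule: take the coincident point's value where finite
        for t in np.nonzero(exact.any(axis=1))[0]:
            j = np.nonzero(exact[t])[0][0]
            hit = finite[t, j]
            out[t, hit, v] = vals[t, j, hit]
    return TractSeries(
        list(tract_ids), centroids, field.dates, list(field.pollutants), out,
        attrs={"idw_power": power, "idw_k": k},
    )


def coarse_fraction(pm10, pm25) -> tuple[np.ndarray | pd.Series, int]:
    """PM10 minus PM2.5, clamped at zero.

    Independently estimated PM10 and PM2.5 can cross; a mass fraction is
    physically nonnegative, so negative differences are clamped to 0 and
    counted.  Returns ``(coarse, n_clamped)``.
    """
    if isinstance(pm10, pd.Series) and isinstance(pm25, pd.Series):
        if not pm10.index.equals(pm25.index):
            raise ValueError("misaligned indices between PM10 and PM2.5")
        diff = pm10 - pm25
    else:
        pm10 = np.asarray(pm10, dtype=float)
        pm25 = np.asarray(pm25, dtype=float)
        if pm10.shape != pm25.shape:
            raise ValueError("misaligned shapes between PM10 and PM2.5")
        diff = pm10 - pm25
    n_clamped = int(np.nansum(np.asarray(diff) < 0))
    return diff.clip(0), n_clamped


def add_coarse_fraction(ts: TractSeries) -> int:
    """Attach ``PM10-2.5`` to a series holding PM10 and PM2.5; returns clamp count."""
    coarse, n_clamped = coarse_fraction(ts.var("PM10"), ts.var("PM2.5"))
    ts.add_variable("PM10-2.5", coarse)
    ts.attrs["coarse_fraction_clamped"] = n_clamped
    return n_clamped


def moving_average_3day(series: pd.Series, target_date) -> float:
    """Mean of a daily series over lag days 0, 1, 2 relative to ``target_date``.

    Returns NaN (flagged missing) when any of the three days is absent from
    the index or NaN — the caller must drop such windows.
    """
    target = pd.Timestamp(target_date).normalize()
    vals = []
    for lag in (0, 1, 2):
        day = target - pd.Timedelta(days=lag)
        if day not in series.index:
            return float("nan")
        vals.append(series.loc[day])
    vals = np.asarray(vals, dtype=float)
    return float(vals.mean())  # NaN propagates if any day missing


def rolling_3dma(values: np.ndarray) -> np.ndarray:
    """Vectorized 3-day moving average along the last (day) axis.

    The first two positions and any window containing a NaN come back NaN.
    """
    values = np.asarray(values, dtype=float)
    out = np.full_like(values, np.nan)
    out[..., 2:] = (values[..., 2:] + values[..., 1:-1] + values[..., :-2]) / 3.0
    return out


def seasonal_spearman(ts: TractSeries, season: str, variables=None) -> pd.DataFrame:
    """Season-stratified Spearman correlations between collapsed daily series.

    Each variable is averaged across tracts per day, collapsed over the whole
    study period by 365-scale day of year, subset to the season's day-of-year
    range, and rank-correlated pairwise.  Undefined correlations (constant
    collapsed series) are reported as NaN.
    """
    if variables is None:
        variables = list(ts.variables)
    first, last = season_doy_range(season)
    doys = np.array([day_of_year_365(d) for d in ts.dates])
    in_season = (doys >= first) & (doys <= last)
    if len(np.unique(doys[in_season])) < 3:
        raise ValueError("need at least 3 distinct season days")

    collapsed = {}
    for name in variables:
        daily = np.nanmean(ts.var(name), axis=0)  # across tracts
        by_doy = (
            pd.Series(daily[in_season])
            .groupby(doys[in_season])
            .mean()
            .sort_index()
        )
        collapsed[name] = by_doy
    frame = pd.DataFrame(collapsed)

    p = len(variables)
    mat = np.full((p, p), np.nan)
    for i in range(p):
        for j in range(i, p):
            xi = frame.iloc[:, i].to_numpy()
            xj = frame.iloc[:, j].to_numpy()
            ok = np.isfinite(xi) & np.isfinite(xj)
            if i == j:
                mat[i, j] = 1.0
                continue
            if np.ptp(xi[ok]) == 0 or np.ptp(xj[ok]) == 0:
                continue  # undefined, reported missing
            rho = spearmanr(xi[ok], xj[ok]).statistic
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=variables, columns=variables)


def plot_correlation_heatmap(matrix: pd.DataFrame, path=None, title=None):
    """Convenience heatmap of a correlation matrix (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
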