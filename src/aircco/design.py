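"""Time-stratified case-crossover dataset construction.

Builds the model-ready table from visit records and tract-level exposures:
season assignment from the case day, year-month-day-of-week stratum
indexing, referent-window selection matched on year, month and day of week,
3-day-moving-average covariate assembly, mean-centering, and a pairwise
collinearity screen with a fixed drop-priority list.
"""

from __future__ import annotations

import calendar
import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import TractSeries, rolling_3dma
from .seasons import SEASONS, Season, assign_season

__all__ = [
    "Season",
    "assign_season",
    "stratum_index",
    "select_referents",
    "build_rows",
    "BuildLog",
    "center_covariates",
    "collinearity_screen",
    "DEFAULT_COVARIATES",
    "INTERACTION",
]

logger = logging.getLogger(__name__)

#: main-effect covariates entering the screen; PM10 itself is excluded in
#: favour of the coarse fraction, which separates it from PM2.5
DEFAULT_COVARIATES = (
    "NOx", "O3", "SO2", "CO", "PM2.5", "PM10-2.5", "temperature", "dewpoint",
)

#: name of the temperature x dewpoint interaction column
INTERACTION = "temp_x_dewp"

#: drop-priority order for collinear pairs (first listed member is dropped)
DROP_PRIORITY = ("CO", "dewpoint", "SO2")


def stratum_index(date, start_year: int = 2005, n_years: int = 10) -> int:
    """Bijective 1-based index of (year, month, day-of-week).

    A 10-year study yields 10 x 12 x 7 = 840 possible strata.  Referent dates
    matched on year, month and day of week map to the same index as their
    case by construction.
    """
    date = _as_date(date)
    if not (start_year <= date.year < start_year + n_years):
        raise ValueError(
            f"date {date} outside study years {start_year}..{start_year + n_years - 1}"
        )
    return (
        (date.year - start_year) * 84 + (date.month - 1) * 7 + date.weekday() + 1
    )


def select_referents(case_date, rng: np.random.Generator) -> list[dt.date]:
    """Referent dates for a case: same year, month and day of week.

    All candidate dates in the case's month sharing its day of week
    (excluding the case date itself) are eligible; when more than three are
    available, three are sampled uniformly without replacement with the
    supplied generator.  A weekday occurs 4 or 5 times per month, so 3 or 4
    candidates exist and at most 3 are returned.
    """
    case = _as_date(case_date)
    n_days = calendar.monthrange(case.year, case.month)[1]
    candidates = [
        d
        for day in range(1, n_days + 1)
        if (d := dt.date(case.year, case.month, day)).weekday() == case.weekday()
        and d != case
    ]
    if len(candidates) > 3:
        picks = rng.choice(len(candidates), size=3, replace=False)
        candidates = [candidates[i] for i in sorted(picks)]
    return candidates


@dataclass
class BuildLog:
    """Counts of windows discarded while assembling the case-crossover table."""

    n_visits: int = 0
    n_visits_dropped: int = 0
    n_referents_dropped: int = 0
    dropped_visit_ids: list = field(default_factory=list)


def build_rows(
    visits: pd.DataFrame,
    exposures: TractSeries,
    rng: np.random.Generator,
    covariates=None,
    start_year: int | None = None,
    n_years: int | None = None,
) -> tuple[pd.DataFrame, BuildLog]:
    """Assemble one case row plus up to three referent rows per visit.

    Covariates are 3-day moving averages of each exposure variable at the
    visit's tract, centred on the window date.  Visits whose case-window 3DMA
    is unavailable are dropped entirely; referent windows with missing 3DMAs
    are dropped individually.  All of a visit's rows share the stratum index
    and the season label of the case day.
    """
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES if c in exposures.variables]
    missing = [c for c in covariates if c not in exposures.variables]
    if missing:
        raise KeyError(f"covariates not in exposure series: {missing}")
    if start_year is None:
        start_year = exposures.dates[0].year
    if n_years is None:
        n_years = exposures.dates[-1].year - start_year + 1

    x3 = np.stack([rolling_3dma(exposures.var(c)) for c in covariates], axis=2)
    log = BuildLog(n_visits=len(visits))
    records: list[tuple] = []

    for visit_id, date, tract in visits[["visit_id", "date", "tract_id"]].itertuples(
        index=False
    ):
        case_date = pd.Timestamp(date).normalize()
        try:
            ti = exposures.tract_index(tract)
            di = exposures.date_index(case_date)
        except KeyError:
            log.n_visits_dropped += 1
            log.dropped_visit_ids.append(visit_id)
            continue
        case_cov = x3[ti, di]
        if not np.all(np.isfinite(case_cov)):
            log.n_visits_dropped += 1
            log.dropped_visit_ids.append(visit_id)
            continue
        stratum = stratum_index(case_date, start_year, n_years)
        season = assign_season(case_date)
        records.append(
            (visit_id, 1, 1, case_date, stratum, season, *case_cov)
        )
        j = 2
        for ref in select_referents(case_date, rng):
            try:
                rdi = exposures.date_index(ref)
            except KeyError:
                log.n_referents_dropped += 1
                continue
            ref_cov = x3[ti, rdi]
            if not np.all(np.isfinite(ref_cov)):
                log.n_referents_dropped += 1
                continue
            records.append(
                (visit_id, j, 0, pd.Timestamp(ref), stratum, season, *ref_cov)
            )
            j += 1

    df = pd.DataFrame(
        records,
        columns=["visit_id", "j", "y", "window_date", "stratum", "season",
                 *covariates],
    )
    if log.n_visits_dropped or log.n_referents_dropped:
        logger.info(
            "build_rows: dropped %d visits and %d referent windows "
            "(unavailable 3-day windows)",
            log.n_visits_dropped, log.n_referents_dropped,
        )
    return df, log


def center_covariates(
    rows: pd.DataFrame,
    covariates,
    scope: str = "overall",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Mean-centre covariates over the scoped rows and add the interaction.

    ``scope`` is ``"overall"`` (all rows) or a season name (that season's
    rows, selected by the case day's season label).  The temperature x
    dewpoint interaction is the product of the *centred* main effects,
    itself re-centred, and is added whenever both weather variables are
    present in the table — the interaction stays in the model even when the
    dewpoint main effect is screened out.
    """
    if len(rows) == 0:
        raise ValueError("cannot centre an empty table")
    if scope != "overall":
        if scope not in SEASONS:
            raise ValueError(f"unknown scope {scope!r}")
        rows = rows.loc[rows["season"] == scope]
        if len(rows) == 0:
            raise ValueError(f"no rows in season {scope!r}")
    out = rows.copy()
    means: dict[str, float] = {}
    for cov in covariates:
        mu = float(out[cov].mean())
        out[cov] = out[cov] - mu
        means[cov] = mu
    if "temperature" in out.columns and "dewpoint" in out.columns:
        t = out["temperature"] - float(out["temperature"].mean())
        d = out["dewpoint"] - float(out["dewpoint"].mean())
        inter = t * d
        mu = float(inter.mean())
        out[INTERACTION] = inter - mu
        means[INTERACTION] = mu
    return out, means


def _vif(corr: np.ndarray) -> np.ndarray:
    """Variance inflation factors from a correlation matrix (diag of inverse)."""
    try:
        return np.diag(np.linalg.inv(corr))
    except np.linalg.LinAlgError:
        return np.diag(np.linalg.pinv(corr))


def collinearity_screen(
    rows: pd.DataFrame,
    covariates,
    threshold: float = 0.9,
    priority=DROP_PRIORITY,
) -> tuple[list[str], list[dict]]:
    """Iteratively remove covariates until all pairwise |Pearson r| <= threshold.

    For each offending pair, the member appearing earliest in ``priority``
    is dropped; if neither is listed, the one with the larger variance
    inflation factor within the current candidate set goes.  Returns the
    retained names (original order) and a removal log.
    """
    if len(covariates) < 2:
        raise ValueError("need at least 2 covariates to screen")
    cands = list(covariates)
    removals: list[dict] = []
    while len(cands) > 1:
        corr = rows[cands].corr().to_numpy()
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        r = corr[i, j]
        if abs(r) <= threshold:
            break
        a, b = cands[i], cands[j]
        drop = next((p for p in priority if p in (a, b)), None)
        if drop is None:
            full = rows[cands].corr().to_numpy()
            full = np.nan_to_num(full, nan=0.0)
            np.fill_diagonal(full, 1.0)
            vifs = _vif(full)
            drop = a if vifs[i] >= vifs[j] else b
        kept = b if drop == a else a
        removals.append({"dropped": drop, "kept": kept, "abs_r": float(abs(r))})
        logger.info(
            "collinearity screen: removed %s (|r|=%.3f with %s)", drop, abs(r), kept
        )
        cands.remove(drop)
    if len(cands) == 1:
        warnings.warn("all covariates mutually collinear; retaining one")
    return cands, removals


def _as_date(date) -> dt.date:
    if isinstance(date, pd.Timestamp):
        return date.date()
    if isinstance(date, dt.datetime):
        return date.date()
    if isinstance(date, dt.date):
        return date
    return pd.Timestamp(date).date()
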