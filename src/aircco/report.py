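"""Summary surfaces: IQR-scaled odds ratios, seasonal burden, descriptive tables.

Coefficients are reported as the odds of an interquartile-range increase in
an exposure's 3-day moving average, ``OR_IQR = exp(beta * IQR)``, with
equal-tailed 95% credible intervals from the posterior percentiles.  Burden
summaries give visit counts and mean daily visits per asthma season;
stratified tables give counts, percentages and chi-square comparisons
against a reference population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seasons import SEASON_NAMES, assign_season, season_day_count

__all__ = [
    "ORResult",
    "or_iqr",
    "compute_iqr",
    "make_or_table",
    "format_or_table",
    "BurdenSummary",
    "burden_summary",
    "mean_daily_visits",
    "stratified_table",
]


@dataclass(frozen=True)
class ORResult:
    """OR_IQR point estimate with 95% credible interval."""

    point: float
    lower: float
    upper: float
    iqr: float

    @property
    def significant(self) -> bool:
        """Interval excludes the null odds ratio of 1."""
        return self.lower > 1.0 or self.upper < 1.0


def compute_iqr(values, scope_mask=None) -> float:
    """Interquartile range (75th minus 25th percentile, linear interpolation).

    Computed over case and referent window values within the model's scope
    (all rows for the overall model, one season's rows for a season model).
    """
    values = np.asarray(values, dtype=float)
    if scope_mask is not None:
        values = values[np.asarray(scope_mask, dtype=bool)]
    values = values[np.isfinite(values)]
    if values.size < 4:
        raise ValueError("need at least 4 values to compute an IQR")
    q25, q75 = np.percentile(values, [25.0, 75.0], method="linear")
    return float(q75 - q25)


def or_iqr(beta_draws, iqr: float, point: str = "median") -> ORResult:
    """Odds ratio per IQR increase, with equal-tailed 95% credible interval.

    ``beta_draws`` are posterior draws of a per-native-unit log-odds
    coefficient; each draw is transformed as ``exp(beta * iqr)`` and the
    posterior median (or mean) and 2.5th/97.5th percentiles are reported.
    """
    if iqr <= 0:
        raise ValueError("IQR must be > 0")
    beta_draws = np.asarray(beta_draws, dtype=float)
    if beta_draws.size < 100:
        raise ValueError("need at least 100 posterior draws")
    ors = np.exp(beta_draws * iqr)
    centre = float(np.median(ors) if point == "median" else np.mean(ors))
    lo, hi = np.percentile(ors, [2.5, 97.5], method="linear")
    return ORResult(point=centre, lower=float(lo), upper=float(hi), iqr=float(iqr))


def make_or_table(results: dict[str, dict[str, ORResult]]) -> pd.DataFrame:
    """Long-format OR table: one row per (model, covariate).

    ``results`` maps model name (overall or a season) to a mapping of
    covariate name -> :class:`ORResult`.
    """
    rows = []
    for model, by_cov in results.items():
        for cov, r in by_cov.items():
            rows.append(
                {
                    "model": model,
                    "covariate": cov,
                    "or_iqr": round(r.point, 3),
                    "ci_lower": round(r.lower, 3),
                    "ci_upper": round(r.upper, 3),
                    "iqr": round(r.iqr, 3),
                    "significant": r.significant,
                }
            )
    return pd.DataFrame(rows)


def format_or_table(table: pd.DataFrame, units: dict[str, str] | None = None) -> str:
    """Three-line cell layout: OR / (interval) / IQR with units, per model column."""
    units = units or {}
    models = list(dict.fromkeys(table["model"]))
    covs = list(dict.fromkeys(table["covariate"]))
    width = max(22, max((len(m) for m in models), default=10) + 2)
    lines = ["Variable".ljust(16) + "".join(m.ljust(width) for m in models)]
    for cov in covs:
        cells = {m: "" for m in models}
        sub = table[table["covariate"] == cov]
        l1, l2, l3 = [cov.ljust(16)], ["".ljust(16)], ["".ljust(16)]
        for m in models:
            row = sub[sub["model"] == m]
            if len(row) == 0:
                l1.append("N/A".ljust(width))
                l2.append("".ljust(width))
                l3.append("".ljust(width))
                continue
            r = row.iloc[0]
            star = "*" if r["significant"] else ""
            l1.append(f"{r['or_iqr']:.3f}{star}".ljust(width))
            l2.append(f"({r['ci_lower']:.3f},{r['ci_upper']:.3f})".ljust(width))
            l3.append(f"{r['iqr']:.3f} {units.get(cov, '')}".rstrip().ljust(width))
        lines += ["".join(l1), "".join(l2), "".join(l3)]
    lines.append("* 95% credible interval excludes 1")
    return "\n".join(lines)


def mean_daily_visits(count: int, season: str, years) -> float:
    """Season visit count divided by the season's calendar days, 1 decimal."""
    days = season_day_count(season, years)
    if days == 0:
        return 0.0
    return round(count / days, 1)


@dataclass
class BurdenSummary:
    """Per-season counts, day counts and mean daily visits over the study years."""

    counts: dict[str, int]
    day_counts: dict[str, int]
    means: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "season": list(self.counts),
                "visits": list(self.counts.values()),
                "season_days": list(self.day_counts.values()),
                "mean_daily_visits": list(self.means.values()),
            }
        )


def burden_summary(visits: pd.DataFrame, years) -> BurdenSummary:
    """Seasonal visit burden: counts and visits/day/year by asthma season."""
    years = list(years)
    seasons = (
        visits["date"].map(assign_season)
        if len(visits)
        else pd.Series([], dtype=object)
    )
    counts = {name: int((seasons == name).sum()) for name in SEASON_NAMES}
    day_counts = {name: season_day_count(name, years) for name in SEASON_NAMES}
    means = {
        name: mean_daily_visits(counts[name], name, years) for name in SEASON_NAMES
    }
    return BurdenSummary(counts=counts, day_counts=day_counts, means=means)


def stratified_table(
    visits: pd.DataFrame,
    stratifications: dict[str, list[str]] | None = None,
    reference: dict[str, dict[str, int]] | None = None,
) -> pd.DataFrame:
    """Counts and one-decimal percentages per stratum, with chi-square tests.

    When a reference population's counts are supplied for a stratification,
    the visit distribution is compared to the reference distribution with a
    chi-square goodness-of-fit test; expected cells below 5 are annotated.
    """
    if stratifications is None:
        stratifications = {
            col: sorted(visits[col].dropna().unique().tolist())
            for col in ("sex", "age_group", "race", "payor", "region")
            if col in visits.columns
        }
    total = len(visits)
    rows = []
    for strat, levels in stratifications.items():
        observed = np.array(
            [int((visits[strat] == lev).sum()) for lev in levels], dtype=float
        )
        p_value, note = np.nan, ""
        if reference is not None and strat in reference:
            ref = np.array([reference[strat][lev] for lev in levels], dtype=float)
            expected = ref / ref.sum() * observed.sum()
            if (expected < 5).any():
                note = "expected cell count < 5"
            if len(levels) < 2 or np.allclose(expected, 0):
                note = (note + "; " if note else "") + "degenerate chi-square"
            else:
                chi2 = stats.chisquare(observed, f_exp=expected)
                p_value = float(chi2.pvalue)
        elif len(levels) < 2:
            note = "degenerate chi-square"
        for lev, n in zip(levels, observed):
            pct = round(100.0 * n / total, 1) if total else 0.0
            rows.append(
                {
                    "stratification": strat,
                    "stratum": lev,
                    "n": int(n),
                    "pct": pct,
                    "p_value": p_value,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)
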