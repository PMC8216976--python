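"""Summaries of hourly rock-temperature logger series.

Loggers sample hourly at fixed shore positions across a hot (summer) and a
cool (winter) season.  The summaries here are the ones that matter for
high-shore ectotherms: seasonal extremes, how often days get hotter than a
physiological threshold, and the margin between seasonal maxima and lethal
limits (LT50) or sublethal breakpoints (ABT, the Arrhenius breakpoint
temperature of heart rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import pandas as pd

__all__ = [
    "TemperatureSeries",
    "ToleranceConstants",
    "seasonal_range",
    "pct_days_exceeding",
    "pct_readings_exceeding",
    "safety_margin",
]

_REQUIRED = ("timestamp", "logger", "site", "temp_c")


@dataclass
class TemperatureSeries:
    """Hourly temperature readings with optional season labels.

    Wraps a tidy frame with columns ``timestamp, logger, site, temp_c``
    and optionally ``season``.  Timestamps must be strictly increasing per
    logger; departures from hourly cadence are allowed but flagged in
    ``gap_warnings``.
    """

    frame: pd.DataFrame
    gap_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"temperature frame missing columns: {missing}")
        df = self.frame.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        df = df.sort_values(["logger", "timestamp"], kind="stable").reset_index(
            drop=True
        )
        for logger, grp in df.groupby("logger"):
            diffs = grp["timestamp"].diff().dropna()
            if (diffs <= pd.Timedelta(0)).any():
                raise ValueError(
                    f"timestamps not strictly increasing for logger {logger!r}"
                )
            n_gaps = int((diffs != pd.Timedelta(hours=1)).sum())
            if n_gaps:
                self.gap_warnings.append(
                    f"logger {logger!r}: {n_gaps} departures from hourly cadence"
                )
        self.frame = df

    def with_seasons(
        self, season_of: Callable | Mapping | str
    ) -> "TemperatureSeries":
        """Return a copy with a ``season`` column added."""
        df = self.frame.copy()
        if callable(season_of):
            df["season"] = df["timestamp"].map(season_of)
        elif isinstance(season_of, str):
            df["season"] = season_of
        else:
            df["season"] = df["timestamp"].dt.date.map(
                lambda d: season_of[d] if d in season_of else None
            )
            if df["season"].isna().any():
                raise ValueError("season mapping does not cover all dates")
        return TemperatureSeries(df)

    def _season_slice(self, season: str | None) -> pd.DataFrame:
        df = self.frame
        if season is None:
            return df
        if "season" not in df.columns:
            raise ValueError("series has no season labels; call with_seasons()")
        out = df[df["season"] == season]
        if out.empty:
            raise ValueError(f"no readings in season {season!r}")
        return out


def seasonal_range(
    series: TemperatureSeries, season: str | None = None
) -> tuple[float, float]:
    """(min, max) temperature over all loggers and sites in a season."""
    df = series._season_slice(season)
    return float(df["temp_c"].min()), float(df["temp_c"].max())


def _daily_stat(
    df: pd.DataFrame, daily_stat: str, pool_loggers: str
) -> pd.Series:
    """One value per local calendar date: daily max (or mean) per logger,
    pooled across loggers by max (a day is hot if any logger was) or mean."""
    if daily_stat not in ("max", "mean"):
        raise ValueError("daily_stat must be 'max' or 'mean'")
    if pool_loggers not in ("max", "mean"):
        raise ValueError("pool_loggers must be 'max' or 'mean'")
    per_logger = (
        df.assign(date=df["timestamp"].dt.date)
        .groupby(["date", "logger"])["temp_c"]
        .agg(daily_stat)
    )
    return per_logger.groupby("date").agg(pool_loggers)


def pct_days_exceeding(
    series: TemperatureSeries,
    threshold: float,
    site: str | None = None,
    *,
    season: str | None = None,
    daily_stat: str = "max",
    pool_loggers: str = "max",
    strict: bool = True,
) -> float:
    """Percent of days whose daily statistic exceeds a threshold.

    A day is a local calendar date with at least one reading.  By default
    the daily statistic is the maximum over the day's readings, pooled
    across a site's loggers by max, and the comparison is strict
    (``daily max > threshold``); pass ``strict=False`` for ``>=``.
    """
    df = series._season_slice(season)
    if site is not None:
        df = df[df["site"] == site]
        if df.empty:
            raise ValueError(f"no readings for site {site!r}")
    daily = _daily_stat(df, daily_stat, pool_loggers)
    if daily.empty:
        raise ValueError("no days with data")
    hot = (daily > threshold) if strict else (daily >= threshold)
    return 100.0 * float(hot.mean())


def pct_readings_exceeding(
    series: TemperatureSeries,
    threshold: float,
    site: str | None = None,
    *,
    season: str | None = None,
    strict: bool = True,
) -> float:
    """Percent of individual readings above a threshold (the alternative
    reading-level interpretation of 'day temperatures exceeding T')."""
    df = series._season_slice(season)
    if site is not None:
        df = df[df["site"] == site]
        if df.empty:
            raise ValueError(f"no readings for site {site!r}")
    hot = (df["temp_c"] > threshold) if strict else (df["temp_c"] >= threshold)
    return 100.0 * float(hot.mean())


@dataclass(frozen=True)
class ToleranceConstants:
    """Species thermal-tolerance constants: lethal LT50 and optional ABT (°C)."""

    lt50: Mapping[str, float]
    abt: float | None = None

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.lt50.values()):
            raise ValueError("LT50 values must be positive")


def safety_margin(
    series: TemperatureSeries, tolerances: ToleranceConstants
) -> pd.DataFrame:
    """Thermal-safety margins per season and species.

    margin = LT50 − seasonal maximum; when an ABT is supplied, the percent
    of hourly readings above it is reported alongside.  Returns a tidy
    frame with columns ``season, species, seasonal_max, lt50, margin_c``
    (+ ``pct_hours_above_abt``).
    """
    df = series.frame
    seasons = (
        sorted(df["season"].dropna().unique()) if "season" in df.columns else [None]
    )
    rows = []
    for season in seasons:
        sl = series._season_slice(season)
        smax = float(sl["temp_c"].max())
        for species, lt50 in tolerances.lt50.items():
            row = {
                "season": season if season is not None else "all",
                "species": species,
                "seasonal_max": smax,
                "lt50": lt50,
                "margin_c": lt50 - smax,
            }
            if tolerances.abt is not None:
                row["pct_hours_above_abt"] = 100.0 * float(
                    (sl["temp_c"] > tolerances.abt).mean()
                )
            rows.append(row)
    return pd.DataFrame(rows)
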