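"""Scan-sampling activity budgets from quadrat survey records.

Hourly quadrat scans record, for every visible snail, the set of behaviors
it is performing.  Each behavior belongs to one fitness-associated
activity category (reproduction, foraging, stress mitigation, inactive).
Two scoring rules matter:

* within one category an individual is scored once, however many of that
  category's behaviors it shows (e.g. aggregating while in a crevice);
* across categories an individual may be scored several times (e.g. a
  female mating while moving), so behavior percentages within an hour can
  sum above 100%.

Any movement is ascribed to foraging, since grazing cannot be observed
directly in the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import datetime
from typing import Callable, Iterable, Mapping

import pandas as pd

__all__ = [
    "CATEGORIES",
    "DEFAULT_ETHOGRAM",
    "Ethogram",
    "ScanRecord",
    "score_individual",
    "hourly_budget",
    "seasonal_allocation",
]

#: The four fitness-associated activity categories.
CATEGORIES: tuple[str, ...] = (
    "reproduction",
    "foraging",
    "stress_mitigation",
    "inactive",
)

_DEFAULT_MAP: dict[str, str] = {
    "mating": "reproduction",
    "fighting": "reproduction",
    "moving": "foraging",
    "turning": "foraging",
    "in_crevice": "stress_mitigation",
    "towering": "stress_mitigation",
    "standing": "stress_mitigation",
    "aggregating": "stress_mitigation",
    "stationary": "inactive",
}


@dataclass(frozen=True)
class Ethogram:
    """Mapping from behavior names to fitness-associated activity categories."""

    behaviors: Mapping[str, str] = dc_field(
        default_factory=lambda: dict(_DEFAULT_MAP)
    )

    def __post_init__(self) -> None:
        bad = {b: c for b, c in self.behaviors.items() if c not in CATEGORIES}
        if bad:
            raise ValueError(f"behaviors mapped outside {CATEGORIES}: {bad}")

    def category_of(self, behavior: str) -> str:
        try:
            return self.behaviors[behavior]
        except KeyError:
            raise ValueError(f"unknown behavior {behavior!r}") from None

    @property
    def behavior_names(self) -> tuple[str, ...]:
        return tuple(self.behaviors)


DEFAULT_ETHOGRAM = Ethogram()


@dataclass(frozen=True)
class ScanRecord:
    """One individual in one hourly quadrat scan."""

    timestamp: datetime
    quadrat: str
    species: str
    individual: str
    behaviors: frozenset[str]

    def __post_init__(self) -> None:
        if not self.behaviors:
            raise ValueError("behavior set must be non-empty")


def score_individual(
    behavior_set: Iterable[str], ethogram: Ethogram = DEFAULT_ETHOGRAM
) -> dict[str, int]:
    """Score one individual's behavior set into 0/1 category flags.

    A category with one or more matching behaviors contributes exactly 1,
    avoiding bias toward categories with many constituent behaviors.
    """
    behaviors = set(behavior_set)
    if not behaviors:
        raise ValueError("behavior set must be non-empty")
    flags = {c: 0 for c in CATEGORIES}
    for b in behaviors:
        flags[ethogram.category_of(b)] = 1
    return flags


def _frame(records: Iterable[ScanRecord]) -> pd.DataFrame:
    rows = [
        {
            "timestamp": r.timestamp,
            "quadrat": r.quadrat,
            "species": r.species,
            "individual": r.individual,
            "behaviors": r.behaviors,
        }
        for r in records
    ]
    if not rows:
        raise ValueError("no scan records supplied")
    df = pd.DataFrame(rows)
    # hours bin on the hour, half-open [h, h+1)
    df["hour"] = pd.to_datetime(df["timestamp"]).dt.floor("h")
    return df


def hourly_budget(
    records: Iterable[ScanRecord], ethogram: Ethogram = DEFAULT_ETHOGRAM
) -> pd.DataFrame:
    """Percentage of scanned individuals showing each behavior, per hour.

    Records are pooled across quadrats within each (hour, species) cell;
    the denominator is the number of individuals scanned in that cell.
    Hours with no records simply do not appear (missing, not 0%).

    Returns a tidy frame with columns ``hour, species, behavior, pct,
    n_individuals``.
    """
    df = _frame(records)
    for r in df.itertuples():
        for b in r.behaviors:
            ethogram.category_of(b)  # validate early, with behavior name
    out = []
    for (hour, species), grp in df.groupby(["hour", "species"], sort=True):
        n = len(grp)
        for behavior in ethogram.behavior_names:
            shown = sum(behavior in bs for bs in grp["behaviors"])
            out.append(
                {
                    "hour": hour,
                    "species": species,
                    "behavior": behavior,
                    "pct": 100.0 * shown / n,
                    "n_individuals": n,
                }
            )
    return pd.DataFrame(out)


def seasonal_allocation(
    records: Iterable[ScanRecord],
    ethogram: Ethogram = DEFAULT_ETHOGRAM,
    season_of: Callable[[datetime], str] | Mapping | str | None = None,
    *,
    basis: str = "pooled",
) -> pd.DataFrame:
    """Allocation of individual-scans across activity categories per season.

    Each individual-scan contributes a 0/1 flag per category (see
    :func:`score_individual`).  With ``basis="pooled"`` (default) the
    allocation is ``100 × flagged individual-scans / total individual-
    scans`` pooled over all hours and quadrats in the season — robust to
    unequal per-hour abundance.  ``basis="hourly_mean"`` instead averages
    the hourly category percentages, weighting every hour equally.

    ``season_of`` labels records: a callable on the timestamp, a mapping
    from ``date`` to season name, or a single season label (default
    ``"all"``).  Allocations sum to exactly 100% when no individual shows
    behaviors from two categories at once, and above 100% otherwise.
    """
    if basis not in ("pooled", "hourly_mean"):
        raise ValueError("basis must be 'pooled' or 'hourly_mean'")
    df = _frame(records)
    if season_of is None:
        df["season"] = "all"
    elif callable(season_of):
        df["season"] = df["timestamp"].map(season_of)
    elif isinstance(season_of, str):
        df["season"] = season_of
    else:
        def lookup(ts: datetime) -> str:
            key = ts.date()
            if key not in season_of:
                raise ValueError(f"no season label for date {key}")
            return season_of[key]

        df["season"] = df["timestamp"].map(lookup)

    flag_rows = [score_individual(bs, ethogram) for bs in df["behaviors"]]
    flags = pd.DataFrame(flag_rows, index=df.index)
    df = pd.concat([df, flags], axis=1)

    out = []
    for (season, species), grp in df.groupby(["season", "species"], sort=True):
        if basis == "pooled":
            pct = grp[list(CATEGORIES)].mean() * 100.0
        else:
            hourly = grp.groupby("hour")[list(CATEGORIES)].mean() * 100.0
            pct = hourly.mean()
        for category in CATEGORIES:
            out.append(
                {
                    "season": season,
                    "species": species,
                    "category": category,
                    "pct": float(pct[category]),
                    "n_scans": len(grp),
                }
            )
    return pd.DataFrame(out)
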