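"""Synthetic data with known ground truth for every analysis stage.

Three generators mirror the three field data streams:

* :func:`simulate_pairs` — sexed two-animal associations drawn from a
  finite pool, with a single preference parameter θ ∈ [0, 1]: each pair
  is, with probability θ, a directed female-marker → male-tracker event
  (one male and one female removed from the remaining pool); otherwise it
  forms by the null model — two uniform draws without replacement and a
  fair orientation.  θ = 0 is exactly the uniform-matching null of
  :mod:`highshore.pairing`.  When a directed event is infeasible (either
  sex exhausted) the pair falls back to null formation; fallbacks are
  counted in the ground-truth record, and they are why the moment
  estimator loses a little ground at high θ on nearly balanced pools.

* :func:`simulate_scans` — hourly quadrat scans of snails whose behavior
  distribution is conditioned on the tidal phase (awash-rising,
  awash-falling, emersed, submerged) of a sinusoidal semidiurnal tide.
  Multifunctional behavior sets (e.g. mating while moving) are drawn with
  configured joint probabilities.

* :func:`simulate_temperatures` — hourly logger series built from a
  day-to-day varying daily peak plus a diurnal cosine, with helpers to
  target a threshold-exceedance fraction or a seasonal min/max envelope.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .budget import CATEGORIES, DEFAULT_ETHOGRAM, Ethogram, ScanRecord
from .pairing import (
    COMBINATIONS,
    PairCountTable,
    SexedPool,
    chi_squared_gof,
    expected_random_pairing,
    monte_carlo_null,
)
from .thermal import TemperatureSeries

__all__ = [
    "PairingScenario",
    "TideScenario",
    "ThermalScenario",
    "simulate_pairs",
    "power_curve",
    "simulate_scans",
    "simulate_temperatures",
    "HOT_SEASON_BEHAVIOR",
    "COOL_SEASON_BEHAVIOR",
]


# ---------------------------------------------------------------------------
# pair tables


@dataclass(frozen=True)
class PairingScenario:
    """Ground-truth configuration for a synthetic pair table.

    ``theta`` is the directed-preference strength; the pool must contain
    exactly ``2 * n_pairs`` individuals.
    """

    males: int
    females: int
    n_pairs: int
    theta: float = 0.0
    association_type: str = "trail_following"
    species: str = "synthetic"
    tide_phase: str = "rising"

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.males + self.females != 2 * self.n_pairs:
            raise ValueError("pool size must equal twice the number of pairs")
        SexedPool(self.males, self.females)  # validates counts

    @property
    def pool(self) -> SexedPool:
        return SexedPool(self.males, self.females)


def simulate_pairs(
    scenario: PairingScenario,
    seed: int | np.random.Generator,
) -> tuple[PairCountTable, dict]:
    """Draw one pair table under the preference model; return (table, truth).

    The truth record carries the scenario parameters plus bookkeeping:
    the number of directed events realized and the number of directed
    attempts that fell back to null pairing because a sex was exhausted.
    """
    rng = np.random.default_rng(seed)
    males, females = scenario.males, scenario.females
    theta = scenario.theta
    counts = dict.fromkeys(COMBINATIONS, 0)
    n_directed = n_fallback = 0

    for _ in range(scenario.n_pairs):
        if theta > 0 and rng.random() < theta:
            if males >= 1 and females >= 1:
                males -= 1
                females -= 1
                counts["FM"] += 1
                n_directed += 1
                continue
            n_fallback += 1
        total = males + females
        i = int(rng.integers(total))
        j = int(rng.integers(total - 1))
        if j >= i:
            j += 1
        s1 = i < males  # True = male
        s2 = j < males
        males -= int(s1) + int(s2)
        females -= int(not s1) + int(not s2)
        if rng.random() < 0.5:
            s1, s2 = s2, s1
        if s1:
            counts["MM" if s2 else "MF"] += 1
        else:
            counts["FM" if s2 else "FF"] += 1

    table = PairCountTable(
        counts=counts,
        association_type=scenario.association_type,
        species=scenario.species,
        tide_phase=scenario.tide_phase,
    )
    truth = {
        "theta": theta,
        "males": scenario.males,
        "females": scenario.females,
        "n_pairs": scenario.n_pairs,
        "n_directed": n_directed,
        "n_fallback": n_fallback,
    }
    return table, truth


def power_curve(
    scenario: PairingScenario,
    thetas: Sequence[float],
    *,
    alpha: float = 0.05,
    replicates: int = 500,
    seed: int | np.random.Generator = 0,
    method: str = "analytic",
    null_replicates: int = 10_000,
) -> pd.DataFrame:
    """Monte-Carlo rejection rate of the goodness-of-fit test per θ.

    ``method="analytic"`` uses the chi-square upper-tail p-value;
    ``method="monte_carlo"`` rejects when the Pearson statistic exceeds
    the (1 − α) quantile of a shared simulated matching null — the
    calibrated test under this generator (see methods note).  Binomial
    standard errors are reported alongside.
    """
    rng = np.random.default_rng(seed)
    expected = expected_random_pairing(scenario.pool, scenario.n_pairs)
    critical = None
    if method == "monte_carlo":
        null = monte_carlo_null(
            scenario.pool, scenario.n_pairs, replicates=null_replicates, seed=rng
        )
        critical = null.critical_value(alpha)
    elif method != "analytic":
        raise ValueError(f"unknown method {method!r}")

    rows = []
    for theta in thetas:
        sc = replace(scenario, theta=float(theta))
        rejections = 0
        for _ in range(replicates):
            table, _ = simulate_pairs(sc, rng)
            res = chi_squared_gof(table, expected)
            if critical is None:
                rejections += res.p_value < alpha
            else:
                rejections += res.chi2 > critical
        p = rejections / replicates
        rows.append(
            {
                "theta": float(theta),
                "power": p,
                "se": math.sqrt(p * (1 - p) / replicates),
                "replicates": replicates,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quadrat scans

PHASES: tuple[str, ...] = (
    "awash-rising",
    "awash-falling",
    "emersed",
    "submerged",
)

BehaviorTable = Mapping[str, Sequence[tuple[frozenset[str], float]]]


def _bt(spec: dict[str, list[tuple[tuple[str, ...], float]]]) -> dict:
    return {
        phase: [(frozenset(bs), p) for bs, p in entries]
        for phase, entries in spec.items()
    }


#: Hot-season phase-conditional behavior-set distributions: activity while
#: awash (foraging, mating — including multifunctional mating+moving),
#: shell posturing and sheltering while emersed.
HOT_SEASON_BEHAVIOR: BehaviorTable = _bt(
    {
        "awash-rising": [
            (("moving",), 0.40),
            (("turning",), 0.08),
            (("mating", "moving"), 0.10),
            (("mating",), 0.05),
            (("fighting",), 0.02),
            (("aggregating",), 0.05),
            (("stationary",), 0.30),
        ],
        "awash-falling": [
            (("moving",), 0.22),
            (("turning",), 0.05),
            (("aggregating",), 0.18),
            (("aggregating", "turning"), 0.05),
            (("towering",), 0.08),
            (("standing",), 0.07),
            (("stationary",), 0.35),
        ],
        "emersed": [
            (("standing",), 0.16),
            (("towering",), 0.10),
            (("in_crevice",), 0.18),
            (("aggregating",), 0.16),
            (("stationary",), 0.40),
        ],
        "submerged": [
            (("moving",), 0.25),
            (("turning",), 0.05),
            (("stationary",), 0.70),
        ],
    }
)

#: Cool-season distributions: crevice occupation and aggregation dominate;
#: no reproduction, no shell posturing (standing/towering), <1% foraging.
COOL_SEASON_BEHAVIOR: BehaviorTable = _bt(
    {
        "awash-rising": [
            (("in_crevice",), 0.45),
            (("aggregating",), 0.33),
            (("moving",), 0.005),
            (("stationary",), 0.215),
        ],
        "awash-falling": [
            (("in_crevice",), 0.45),
            (("aggregating",), 0.33),
            (("moving",), 0.005),
            (("stationary",), 0.215),
        ],
        "emersed": [
            (("in_crevice",), 0.50),
            (("aggregating",), 0.28),
            (("stationary",), 0.22),
        ],
        "submerged": [
            (("in_crevice",), 0.40),
            (("aggregating",), 0.28),
            (("stationary",), 0.32),
        ],
    }
)


@dataclass(frozen=True)
class TideScenario:
    """Sinusoidal semidiurnal tide plus phase-conditional behavior.

    The tide height is ``mean_level + amplitude * sin(2π t / period)``;
    a snail band at ``band_height`` is *awash* while the water level is
    within ``awash_halfwidth`` of the band (rising or falling by the sign
    of the derivative), *submerged* above, *emersed* below.  Transition
    probabilities per phase must sum to 1.
    """

    period_hours: float = 12.42
    amplitude: float = 1.0
    mean_level: float = 1.2
    band_height: float = 1.85
    awash_halfwidth: float = 0.25
    season: str = "hot"
    behavior_table: BehaviorTable = field(
        default_factory=lambda: HOT_SEASON_BEHAVIOR
    )

    def __post_init__(self) -> None:
        for phase, entries in self.behavior_table.items():
            if phase not in PHASES:
                raise ValueError(f"unknown tidal phase {phase!r}")
            total = sum(p for _, p in entries)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"behavior probabilities for {phase!r} sum to {total}, not 1"
                )
        missing = set(PHASES) - set(self.behavior_table)
        if missing:
            raise ValueError(f"behavior table missing phases: {sorted(missing)}")

    def height(self, t_hours: float) -> float:
        return self.mean_level + self.amplitude * math.sin(
            2 * math.pi * t_hours / self.period_hours
        )

    def phase(self, t_hours: float) -> str:
        h = self.height(t_hours)
        rising = math.cos(2 * math.pi * t_hours / self.period_hours) > 0
        if abs(h - self.band_height) <= self.awash_halfwidth:
            return "awash-rising" if rising else "awash-falling"
        return "submerged" if h > self.band_height else "emersed"

    def cool(self) -> "TideScenario":
        """Cool-season variant of this tide."""
        return replace(self, season="cool", behavior_table=COOL_SEASON_BEHAVIOR)


def simulate_scans(
    scenario: TideScenario,
    n_snails: int = 50,
    hours: int = 24,
    seed: int | np.random.Generator = 0,
    *,
    species: str = "synthetic",
    start: datetime | None = None,
    quadrats: int = 10,
    ethogram: Ethogram = DEFAULT_ETHOGRAM,
) -> tuple[list[ScanRecord], dict]:
    """Generate hourly quadrat scan records and a ground-truth record.

    ``n_snails`` individuals are scanned each hour, spread over
    ``quadrats`` quadrats; each draws its behavior set from the scenario's
    distribution for the hour's tidal phase.  The truth record carries the
    configured per-phase distributions, the realized phase of every hour
    and the realized category-flag mix (fraction of individual-scans
    flagging each activity category), for round-trip tests.
    """
    rng = np.random.default_rng(seed)
    if start is None:
        start = datetime(2015, 8, 1, 0, 0)
    records: list[ScanRecord] = []
    flag_totals = dict.fromkeys(CATEGORIES, 0)
    phases: list[str] = []

    for h in range(hours):
        phase = scenario.phase(float(h))
        phases.append(phase)
        entries = scenario.behavior_table[phase]
        probs = np.array([p for _, p in entries])
        ts = start + timedelta(hours=h)
        choices = rng.choice(len(entries), size=n_snails, p=probs / probs.sum())
        for i, c in enumerate(choices):
            behaviors = entries[int(c)][0]
            records.append(
                ScanRecord(
                    timestamp=ts,
                    quadrat=f"Q{i % quadrats + 1}",
                    species=species,
                    individual=f"h{h}i{i}",
                    behaviors=behaviors,
                )
            )
            seen = {ethogram.category_of(b) for b in behaviors}
            for cat in seen:
                flag_totals[cat] += 1

    n_scans = n_snails * hours
    truth = {
        "season": scenario.season,
        "phases": phases,
        "behavior_table": {
            phase: [(sorted(bs), p) for bs, p in entries]
            for phase, entries in scenario.behavior_table.items()
        },
        "realized_category_mix": {
            c: flag_totals[c] / n_scans for c in CATEGORIES
        },
        "n_scans": n_scans,
    }
    return records, truth


# ---------------------------------------------------------------------------
# temperature series


@dataclass(frozen=True)
class ThermalScenario:
    """Hourly logger-series generator for one season at one site.

    Day ``d`` has peak temperature ``P_d ~ N(peak_mean, peak_sd)`` reached
    at ``peak_hour``; within the day the temperature follows
    ``P_d − daily_range * (1 − cos(2π (h − peak_hour) / 24)) / 2`` plus
    reading noise, so with zero noise the daily maximum is ``P_d``
    exactly.  ``envelope`` is a target (min, max); with
    ``pin_envelope=True`` the realized series is affinely rescaled to hit
    it exactly — readings are never clipped.
    """

    days: int = 79
    peak_mean: float = 42.0
    peak_sd: float = 3.0
    daily_range: float = 18.0
    noise_sd: float = 0.0
    peak_hour: int = 14
    season: str = "hot"
    site: str = "S1"
    n_loggers: int = 3
    envelope: tuple[float, float] | None = None
    pin_envelope: bool = False
    start: datetime = datetime(2015, 6, 1)

    def __post_init__(self) -> None:
        if self.days < 1 or self.n_loggers < 1:
            raise ValueError("days and n_loggers must be >= 1")
        if self.peak_sd < 0 or self.noise_sd < 0 or self.daily_range < 0:
            raise ValueError("scale parameters must be non-negative")
        if self.envelope is not None and self.envelope[0] >= self.envelope[1]:
            raise ValueError("envelope must be (low, high) with low < high")

    @classmethod
    def for_exceedance(
        cls, threshold: float, fraction: float, *, peak_sd: float = 3.0, **kw
    ) -> "ThermalScenario":
        """Scenario whose daily maxima exceed ``threshold`` with the given
        long-run ``fraction`` (0 < fraction < 1), via the normal quantile
        of the daily-peak distribution."""
        if not 0.0 < fraction < 1.0:
            raise ValueError("fraction must be in (0, 1)")
        peak_mean = threshold - peak_sd * float(sps.norm.ppf(1.0 - fraction))
        return cls(peak_mean=peak_mean, peak_sd=peak_sd, **kw)

    @classmethod
    def from_envelope(
        cls, low: float, high: float, **kw
    ) -> "ThermalScenario":
        """Scenario rescaled so the realized season spans [low, high]."""
        span = high - low
        return cls(
            peak_mean=high - 2.0,
            peak_sd=2.0,
            daily_range=max(span - 8.0, 1.0),
            envelope=(low, high),
            pin_envelope=True,
            **kw,
        )


def simulate_temperatures(
    scenario: ThermalScenario, seed: int | np.random.Generator = 0
) -> TemperatureSeries:
    """Generate an hourly :class:`~highshore.thermal.TemperatureSeries`."""
    rng = np.random.default_rng(seed)
    hours = np.arange(24)
    diurnal = -scenario.daily_range * (
        1.0 - np.cos(2 * np.pi * (hours - scenario.peak_hour) / 24.0)
    ) / 2.0
    peaks = rng.normal(scenario.peak_mean, scenario.peak_sd, size=scenario.days)

    frames = []
    for logger in range(scenario.n_loggers):
        temp = (peaks[:, None] + diurnal[None, :]).ravel()
        if scenario.noise_sd > 0:
            temp = temp + rng.normal(0.0, scenario.noise_sd, size=temp.size)
        timestamps = [
            scenario.start + timedelta(days=d, hours=int(h))
            for d in range(scenario.days)
            for h in hours
        ]
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": timestamps,
                    "logger": f"{scenario.site}-L{logger + 1}",
                    "site": scenario.site,
                    "temp_c": temp,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)

    if scenario.envelope is not None and scenario.pin_envelope:
        low, high = scenario.envelope
        tmin, tmax = df["temp_c"].min(), df["temp_c"].max()
        df["temp_c"] = low + (df["temp_c"] - tmin) * (high - low) / (tmax - tmin)

    df["season"] = scenario.season
    return TemperatureSeries(df)
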