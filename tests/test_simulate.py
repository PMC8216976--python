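"""Unit tests for the synthetic-data generators.

The pair generator is checked against an exact dynamic-programming oracle
for E[FM]: the generator's state is just (males remaining, females
remaining), so the expectation satisfies a two-dimensional recursion that
can be evaluated exactly and independently of the sampling code.
"""

import sys
from functools import lru_cache

import numpy as np
import pytest

from highshore.budget import CATEGORIES, seasonal_allocation
from highshore.pairing import SexedPool, expected_random_pairing
from highshore.simulate import (
    COOL_SEASON_BEHAVIOR,
    PairingScenario,
    ThermalScenario,
    TideScenario,
    power_curve,
    simulate_pairs,
    simulate_scans,
    simulate_temperatures,
)
from highshore.thermal import pct_days_exceeding, seasonal_range


def expected_fm_exact(males, females, theta):
    """Exact E[FM] of the preference process by recursion over the pool."""
    sys.setrecursionlimit(20_000)

    @lru_cache(maxsize=None)
    def e(a, b):
        t = a + b
        if t == 0:
            return 0.0
        p_mm = a * (a - 1) / (t * (t - 1))
        p_ff = b * (b - 1) / (t * (t - 1))
        p_mix = 2 * a * b / (t * (t - 1))
        null = (
            (p_mm * e(a - 2, b) if a >= 2 else 0.0)
            + (p_ff * e(a, b - 2) if b >= 2 else 0.0)
            + (p_mix * (0.5 + e(a - 1, b - 1)) if a >= 1 and b >= 1 else 0.0)
        )
        if theta > 0 and a >= 1 and b >= 1:
            return theta * (1.0 + e(a - 1, b - 1)) + (1 - theta) * null
        return null

    return e(males, females)


class TestSimulatePairs:
    def test_null_case_matches_closed_form_expectation(self):
        sc = PairingScenario(males=132, females=120, n_pairs=126, theta=0.0)
        rng = np.random.default_rng(11)
        fm = [simulate_pairs(sc, rng)[0].counts["FM"] for _ in range(400)]
        e_fm = expected_random_pairing(SexedPool(132, 120)).expected["FM"]
        se = np.std(fm, ddof=1) / np.sqrt(len(fm))
        assert abs(np.mean(fm) - e_fm) < 3 * se

    def test_full_preference_on_balanced_pool_is_all_fm(self):
        sc = PairingScenario(males=10, females=10, n_pairs=10, theta=1.0)
        table, truth = simulate_pairs(sc, 5)
        assert table.counts["FM"] == 10
        assert truth["n_directed"] == 10 and truth["n_fallback"] == 0

    def test_same_seed_is_deterministic(self):
        sc = PairingScenario(males=30, females=30, n_pairs=30, theta=0.3)
        t1, _ = simulate_pairs(sc, 99)
        t2, _ = simulate_pairs(sc, 99)
        assert t1.counts == t2.counts

    def test_mean_fm_matches_exact_recursion(self):
        sc = PairingScenario(males=20, females=16, n_pairs=18, theta=0.5)
        rng = np.random.default_rng(4)
        fm = [simulate_pairs(sc, rng)[0].counts["FM"] for _ in range(3000)]
        exact = expected_fm_exact(20, 16, 0.5)
        se = np.std(fm, ddof=1) / np.sqrt(len(fm))
        assert abs(np.mean(fm) - exact) < 3 * se

    def test_imbalanced_pool_records_fallbacks_at_high_theta(self):
        sc = PairingScenario(males=2, females=18, n_pairs=10, theta=1.0)
        table, truth = simulate_pairs(sc, 0)
        assert truth["n_directed"] == 2  # only two males available
        assert truth["n_fallback"] == 8
        assert table.n_pairs == 10

    def test_infeasible_scenario_rejected(self):
        with pytest.raises(ValueError):
            PairingScenario(males=5, females=5, n_pairs=6)
        with pytest.raises(ValueError):
            PairingScenario(males=5, females=5, n_pairs=5, theta=1.5)


class TestPowerCurve:
    def test_power_rises_with_theta_and_saturates(self):
        sc = PairingScenario(males=30, females=30, n_pairs=30)
        out = power_curve(sc, [0.0, 0.6, 1.0], replicates=150, seed=8)
        assert out["power"].iloc[0] < 0.25
        assert out["power"].iloc[2] > 0.95
        assert out["power"].is_monotonic_increasing

    def test_unknown_method_rejected(self):
        sc = PairingScenario(males=4, females=4, n_pairs=4)
        with pytest.raises(ValueError):
            power_curve(sc, [0.0], method="bootstrap", seed=1)


class TestSimulateScans:
    def test_stationary_only_phase_yields_pure_inactivity(self):
        sc = TideScenario(
            mean_level=0.0,  # band never wetted -> always emersed
            band_height=5.0,
            behavior_table={
                p: [(frozenset({"stationary"}), 1.0)]
                for p in ("awash-rising", "awash-falling", "emersed", "submerged")
            },
        )
        records, truth = simulate_scans(sc, n_snails=20, hours=6, seed=2)
        pct = seasonal_allocation(records).set_index("category")["pct"]
        assert pct["inactive"] == pytest.approx(100.0)
        assert set(truth["phases"]) == {"emersed"}

    def test_cool_regime_has_no_reproduction_or_posturing(self):
        records, truth = simulate_scans(
            TideScenario().cool(), n_snails=40, hours=24, seed=3
        )
        behaviors = set().union(*(r.behaviors for r in records))
        assert behaviors.isdisjoint({"mating", "fighting", "standing", "towering"})
        assert truth["realized_category_mix"]["reproduction"] == 0.0

    def test_truth_bookkeeping_matches_recomputed_allocation(self):
        records, truth = simulate_scans(TideScenario(), n_snails=30, hours=24, seed=6)
        pct = seasonal_allocation(records).set_index("category")["pct"]
        for c in CATEGORIES:
            assert pct[c] == pytest.approx(100 * truth["realized_category_mix"][c])

    def test_configured_mating_rate_recovered_in_awash_rising_hours(self):
        records, truth = simulate_scans(TideScenario(), n_snails=200, hours=48, seed=9)
        rising_hours = {
            h for h, p in enumerate(truth["phases"]) if p == "awash-rising"
        }
        assert rising_hours, "tide scenario must produce awash-rising hours"
        scans = [r for r in records
                 if (r.timestamp.hour + 24 * (r.timestamp.day - 1)) in rising_hours]
        mating = np.mean([("mating" in r.behaviors) for r in scans])
        se = np.sqrt(0.15 * 0.85 / len(scans))
        assert abs(mating - 0.15) < 3 * se  # configured joint 0.10 + 0.05

    def test_transition_table_must_normalize(self):
        with pytest.raises(ValueError, match="sum"):
            TideScenario(
                behavior_table={
                    "awash-rising": [(frozenset({"moving"}), 0.5)],
                    "awash-falling": [(frozenset({"moving"}), 1.0)],
                    "emersed": [(frozenset({"stationary"}), 1.0)],
                    "submerged": [(frozenset({"stationary"}), 1.0)],
                }
            )


class TestSimulateTemperatures:
    def test_flat_noiseless_scenario_is_constant(self):
        sc = ThermalScenario(days=3, peak_mean=30.0, peak_sd=0.0,
                             daily_range=0.0, noise_sd=0.0)
        series = simulate_temperatures(sc, 0)
        assert seasonal_range(series) == (30.0, 30.0)

    def test_envelope_pinning_hits_target_extrema(self):
        sc = ThermalScenario.from_envelope(24.1, 55.5, days=20, season="hot")
        lo, hi = seasonal_range(simulate_temperatures(sc, 1))
        assert lo == pytest.approx(24.1, abs=1e-9)
        assert hi == pytest.approx(55.5, abs=1e-9)

    def test_exceedance_targeting_within_binomial_noise(self):
        sc = ThermalScenario.for_exceedance(45.0, 0.42, days=79)
        series = simulate_temperatures(sc, 12)
        pct = pct_days_exceeding(series, 45.0)
        se = 100 * np.sqrt(0.42 * 0.58 / 79)
        assert abs(pct - 42.0) < 3 * se

    def test_same_seed_is_deterministic(self):
        sc = ThermalScenario(days=4)
        a = simulate_temperatures(sc, 7).frame["temp_c"]
        b = simulate_temperatures(sc, 7).frame["temp_c"]
        assert (a == b).all()

    def test_hourly_cadence_with_no_gaps(self):
        series = simulate_temperatures(ThermalScenario(days=3), 0)
        assert series.gap_warnings == []
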