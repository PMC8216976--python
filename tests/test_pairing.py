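"""Unit tests for the random-pairing null model and goodness-of-fit."""

import math

import numpy as np
import pytest

from highshore.pairing import (
    COMBINATIONS,
    PairCountTable,
    SexedPool,
    chi_squared_gof,
    derive_pool,
    exact_enumeration,
    expected_random_pairing,
    monte_carlo_null,
    preference_estimate,
)


def table(fm, mm, mf, ff, **kw):
    return PairCountTable(counts={"FM": fm, "MM": mm, "MF": mf, "FF": ff}, **kw)


class TestDerivePool:
    @pytest.mark.parametrize(
        "counts, males, females",
        [
            ((68, 26, 12, 20), 132, 120),
            ((0, 5, 0, 0), 10, 0),
            ((1, 0, 1, 0), 2, 2),
        ],
    )
    def test_individuals_recovered_from_pair_counts(self, counts, males, females):
        pool = derive_pool(table(*counts))
        assert (pool.males, pool.females) == (males, females)
        assert pool.total == 2 * table(*counts).n_pairs

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            table(0, 0, 0, 0)


class TestExpectedRandomPairing:
    def test_single_sex_pool_forces_same_sex_pairs(self):
        exp = expected_random_pairing(SexedPool(0, 6), 3)
        assert exp.expected["FF"] == pytest.approx(3.0)
        assert exp.expected["FM"] == exp.expected["MM"] == exp.expected["MF"] == 0.0

    def test_two_mixed_capable_pairs_match_enumeration(self):
        exp = expected_random_pairing(SexedPool(2, 2), 2)
        assert exp.expected["FM"] == pytest.approx(2 / 3, abs=1e-15)
        assert exp.expected["MF"] == pytest.approx(2 / 3, abs=1e-15)
        assert exp.expected["MM"] == pytest.approx(1 / 3, abs=1e-15)
        assert exp.expected["FF"] == pytest.approx(1 / 3, abs=1e-15)

    def test_inconsistent_pair_count_rejected(self):
        with pytest.raises(ValueError):
            expected_random_pairing(SexedPool(4, 4), 3)

    def test_pool_below_two_rejected(self):
        with pytest.raises(ValueError):
            SexedPool(1, 0)


class TestChiSquaredGof:
    def test_observed_equal_expected_gives_zero_statistic(self):
        obs = table(0, 0, 0, 3)
        res = chi_squared_gof(obs)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_single_sex_pool_drops_categories_and_reduces_df(self):
        res = chi_squared_gof(table(0, 5, 0, 0))
        assert res.retained == ("MM",)
        assert res.df == 0
        assert any("dropped" in w for w in res.warnings)

    def test_small_expectation_warning(self):
        res = chi_squared_gof(table(2, 1, 1, 2))
        assert any("below 5" in w for w in res.warnings)

    def test_mismatched_n_rejected(self):
        exp = expected_random_pairing(SexedPool(4, 4), 4)
        with pytest.raises(ValueError):
            chi_squared_gof(table(1, 1, 1, 0), exp)

    def test_positive_count_in_impossible_category_rejected(self):
        exp = expected_random_pairing(SexedPool(0, 8), 4)
        with pytest.raises(ValueError):
            chi_squared_gof(table(1, 0, 0, 3), exp)

    def test_monte_carlo_p_value_agrees_with_analytic_for_large_effect(self):
        obs = table(68, 26, 12, 20)
        mc = chi_squared_gof(obs, method="monte_carlo", replicates=2000, seed=7)
        assert mc.method == "monte_carlo"
        assert mc.chi2 == pytest.approx(chi_squared_gof(obs).chi2)
        assert mc.p_value == pytest.approx(1 / 2001)  # nothing as extreme

    def test_monte_carlo_requires_seed(self):
        with pytest.raises(ValueError):
            chi_squared_gof(table(3, 3, 3, 3), method="monte_carlo")


class TestMonteCarloNull:
    def test_single_sex_pool_is_degenerate(self):
        null = monte_carlo_null(SexedPool(0, 6), replicates=200, seed=1)
        assert (null.counts[:, 3] == 3).all()  # FF = 3 every replicate

    def test_same_seed_reproduces_distribution(self):
        a = monte_carlo_null(SexedPool(6, 6), replicates=300, seed=42)
        b = monte_carlo_null(SexedPool(6, 6), replicates=300, seed=42)
        assert (a.counts == b.counts).all()

    def test_means_match_closed_form_within_three_se(self):
        pool = SexedPool(132, 120)
        null = monte_carlo_null(pool, replicates=10_000, seed=3)
        exp = expected_random_pairing(pool).expected
        for k in COMBINATIONS:
            se = null.se_counts[k]
            assert abs(null.mean_counts[k] - exp[k]) < 3 * se

    def test_odd_pool_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_null(SexedPool(3, 2), seed=0)


class TestExactEnumeration:
    @pytest.mark.parametrize(
        "males, females, key, value",
        [
            (2, 2, "FM", 2 / 3),
            (1, 1, "FM", 1 / 2),
            (1, 1, "MF", 1 / 2),
            (4, 0, "MM", 2.0),
        ],
    )
    def test_small_pool_expectations(self, males, females, key, value):
        exact = exact_enumeration(SexedPool(males, females))
        assert exact.expected[key] == pytest.approx(value, abs=1e-12)

    def test_distribution_is_normalized(self):
        exact = exact_enumeration(SexedPool(3, 3))
        assert sum(exact.distribution.values()) == pytest.approx(1.0, abs=1e-12)

    def test_pool_above_cap_rejected(self):
        with pytest.raises(ValueError):
            exact_enumeration(SexedPool(10, 10))


class TestPreferenceEstimate:
    def test_published_rising_tide_table(self):
        est = preference_estimate(table(68, 26, 12, 20))
        assert est.theta_hat == pytest.approx(0.386, abs=0.001)
        assert est.expected_fm == pytest.approx(31.55, abs=0.01)

    def test_all_fm_pairs_give_theta_one(self):
        est = preference_estimate(table(10, 0, 0, 0))
        assert est.theta_hat == 1.0
        assert not est.clipped

    def test_deficit_of_fm_clips_to_zero(self):
        est = preference_estimate(table(0, 10, 10, 20))
        assert est.theta_hat == 0.0
        assert est.clipped

    def test_single_sex_pool_rejected(self):
        with pytest.raises(ValueError):
            preference_estimate(table(0, 5, 0, 0))


class TestPrintedTables:
    """The eight published observed→expected/χ² sets, via the fixtures."""

    def test_every_expected_value_matches_print(self, field_tables):
        from conftest import PRINTED

        for key, t in field_tables.items():
            exp = expected_random_pairing(derive_pool(t)).expected
            for combo, printed in PRINTED[key]["expected"].items():
                assert exp[combo] == pytest.approx(printed, abs=0.05), (key, combo)

    def test_every_chi2_and_annotation_matches_print(self, field_tables):
        from conftest import PRINTED

        for key, t in field_tables.items():
            res = chi_squared_gof(t)
            assert res.chi2 == pytest.approx(PRINTED[key]["chi2"], abs=0.02), key
            assert res.df == 3, key
            assert res.p_annotation == PRINTED[key]["annotation"], key

    def test_radiata_falling_ff_count_inferred_and_flagged(self, field_tables):
        t = field_tables[("trail_following", "E. radiata", "falling")]
        assert t.counts["FF"] == 33
        assert t.inferred == ("FF",)
        assert any(
            "inferred" in w for w in chi_squared_gof(t).to_dict()["warnings"]
        )
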