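"""Donor-potential filtering, indirect standardization, and one-sided UCLs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from opometrics.errors import ComputationError, ConfigurationError
from opometrics.performance_metrics import (
    StratumScheme,
    compute_all_measures,
    expected_events,
    identify_donor_potential,
    national_rates,
    standardized_rate,
    ucl95,
    ucl95_standardized,
)


def _deaths(rows):
    return pd.DataFrame(
        rows, columns=["record_id", "year", "age", "inpatient", "calc_cause",
                       "county_of_death", "county_of_residence"]
    )


class TestDonorPotentialFilter:
    def test_age_75_inclusive_boundary(self):
        deaths = _deaths([
            (1, 2018, 75, True, True, "a", "a"),   # counted: 75 or younger
            (2, 2018, 76, True, True, "a", "a"),   # excluded: over 75
        ])
        got = identify_donor_potential(deaths)
        assert got["record_id"].tolist() == [1]

    def test_brute_force_filter_oracle_on_toy_records(self):
        rows = [
            (1, 2018, 40, True, True, "a", "a"),
            (2, 2018, 40, False, True, "a", "a"),
            (3, 2018, 40, True, False, "a", "a"),
            (4, 2018, 90, True, True, "a", "a"),
            (5, 2018, 75, True, True, "a", "a"),
            (6, 2018, 0, True, True, "a", "a"),
            (7, 2018, 40, False, False, "a", "a"),
            (8, 2018, 76, True, True, "a", "a"),
            (9, 2018, 12, True, True, "a", "a"),
            (10, 2018, 12, False, True, "a", "a"),
        ]
        deaths = _deaths(rows)
        oracle = [r[0] for r in rows if r[3] and r[4] and r[2] <= 75]
        assert identify_donor_potential(deaths)["record_id"].tolist() == oracle
        assert len(oracle) == 4


def _counts(potentials, events):
    pot = pd.DataFrame(potentials, columns=["opo", "year", "stratum", "D"])
    ev = pd.DataFrame(events, columns=["opo", "year", "stratum", "donors", "organs", "kidneys"])
    return pot, ev


class TestNationalRates:
    def test_two_strata_arithmetic_oracle(self):
        pot, ev = _counts(
            [("A", 2018, 0, 100), ("A", 2018, 1, 100)],
            [("A", 2018, 0, 20, 20, 20), ("A", 2018, 1, 10, 10, 10)],
        )
        nat = national_rates(pot, ev, 2018)
        assert nat.r.loc[0, "donors"] == pytest.approx(0.2)
        assert nat.r.loc[1, "donors"] == pytest.approx(0.1)
        assert nat.R_nat["donors"] == pytest.approx(0.15)

    def test_single_opo_rates_equal_its_own(self):
        pot, ev = _counts([("A", 2018, 0, 50)], [("A", 2018, 0, 5, 15, 7)])
        nat = national_rates(pot, ev, 2018)
        assert nat.r.loc[0, "donors"] == pytest.approx(0.1)
        assert nat.r.loc[0, "organs"] == pytest.approx(0.3)

    def test_zero_events_give_zero_rates(self):
        pot, ev = _counts([("A", 2018, 0, 50)], [])
        nat = national_rates(pot, ev, 2018)
        assert nat.R_nat["donors"] == 0.0

    def test_zero_national_potential_rejected(self):
        pot, ev = _counts([], [])
        with pytest.raises(ComputationError):
            national_rates(pot, ev, 2018)

    def test_stratum_without_potential_flagged(self):
        pot, ev = _counts([("A", 2018, 0, 50)], [("A", 2018, 1, 1, 1, 1)])
        nat = national_rates(pot, ev, 2018)
        assert nat.flagged_strata == [1]
        assert nat.r.loc[1, "donors"] == 0.0


class TestStandardization:
    def test_expected_events_arithmetic_oracle(self):
        D_s = pd.Series({0: 10, 1: 30})
        r_s = pd.Series({0: 0.2, 1: 0.1})
        assert expected_events(D_s, r_s) == pytest.approx(5.0)

    def test_zero_rates_give_zero_expected(self):
        assert expected_events(pd.Series({0: 10}), pd.Series({0: 0.0})) == 0.0

    def test_national_mix_reduces_to_crude(self):
        # OPO stratum mix proportional to national: E = D * R_nat
        D_s = pd.Series({0: 20, 1: 20})
        r_s = pd.Series({0: 0.2, 1: 0.1})
        E = expected_events(D_s, r_s)
        assert E == pytest.approx(40 * 0.15)

    @pytest.mark.parametrize(
        "O,E,R,expected",
        [(5.0, 5.0, 0.15, 15.0), (4.0, 2.0, 0.1, 20.0), (3.0, 3.0, 0.2, 20.0)],
    )
    def test_standardized_rate_arithmetic(self, O, E, R, expected):
        assert standardized_rate(O, E, R) == pytest.approx(expected)

    def test_zero_expected_with_observed_rejected(self):
        with pytest.raises(ComputationError):
            standardized_rate(1.0, 0.0, 0.1)

    def test_zero_expected_zero_observed_is_zero(self):
        assert standardized_rate(0.0, 0.0, 0.1) == 0.0


class TestUCL:
    def test_all_events_boundary_is_100(self):
        assert ucl95(40, 40) == pytest.approx(100.0)

    def test_zero_events_closed_form(self):
        for n in (5, 20, 58):
            assert ucl95(0, n) == pytest.approx(100 * (1 - 0.05 ** (1 / n)))

    def test_exact_bound_matches_beta_quantile_and_binomial_tail(self):
        u = ucl95(5, 40) / 100
        assert u == pytest.approx(stats.beta.ppf(0.95, 6, 35))
        # brute-force tail condition: P[X <= 5 | p = u] = 0.05
        assert stats.binom.cdf(5, 40, u) == pytest.approx(0.05, abs=1e-9)

    def test_tail_condition_holds_for_all_small_denominators(self):
        for D in range(1, 51):
            O = np.arange(0, D)
            u = ucl95(O, np.full(D, D)) / 100
            tails = stats.binom.cdf(O, D, u)
            assert np.allclose(tails, 0.05, atol=1e-9)

    def test_dominates_point_rate_and_shrinks_with_denominator(self):
        for O, D in [(0, 10), (5, 40), (39, 40)]:
            assert ucl95(O, D) >= 100 * O / D
        # fixed O/D = 0.2, increasing D tightens the exact bound
        bounds = [ucl95(2, 10), ucl95(4, 20), ucl95(10, 50), ucl95(20, 100)]
        assert all(a > b for a, b in zip(bounds, bounds[1:]))

    def test_wilson_and_wald_also_dominate_point_rate(self):
        for method in ("wilson", "wald"):
            assert ucl95(5, 40, method=method) >= 100 * 5 / 40

    def test_poisson_scale_exact_bound(self):
        # count-type measure: one-sided gamma bound on the count
        u = ucl95(120, 40, scale="poisson") / 100
        assert u == pytest.approx(stats.gamma.ppf(0.95, 121) / 40)
        assert stats.poisson.cdf(120, u * 40) == pytest.approx(0.05, abs=1e-9)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ComputationError):
            ucl95(0, 0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            ucl95(1, 10, method="bogus")


class TestStandardizedUCL:
    def test_reduces_to_crude_at_national_mix(self):
        O, D, R = 5, 40, 0.15
        assert ucl95_standardized(O, D, D * R, R) == pytest.approx(ucl95(O, D))

    def test_composition_of_oracles(self):
        O, D, E, R = 5, 40, 5.0, 0.15
        expected = (ucl95(O, D) / 100) * (D / E) * R * 100
        assert ucl95_standardized(O, D, E, R) == pytest.approx(expected)

    def test_doubling_expected_halves_the_bound(self):
        a = ucl95_standardized(5, 40, 4.0, 0.15)
        b = ucl95_standardized(5, 40, 8.0, 0.15)
        assert a == pytest.approx(2 * b)


class TestComputeMeasures:
    def test_raw_rate_is_direct_division(self, tiny_crosswalk):
        deaths = _deaths(
            [(i, 2018, 50, True, True, "a", "a") for i in range(40)]
        )
        donors = pd.DataFrame(
            {
                "donor_id": range(5), "year": [2018] * 5, "age": [50] * 5,
                "hospital_county": ["a"] * 5, "residence_county": ["a"] * 5,
                "organs_transplanted": [3] * 5, "kidneys_transplanted": [1] * 5,
            }
        )
        quintiles = pd.Series({c: q for c, q in zip("abcdef", [1, 2, 3, 4, 5, 5])})
        rates = compute_all_measures(
            deaths, donors, tiny_crosswalk, quintiles, years=[2018], variants=["raw"]
        )
        don = rates[rates["measure"] == "donation"].iloc[0]
        assert don["rate"] == pytest.approx(100 * 5 / 40) == 12.5

    def test_conservation_and_national_totals(self, small_config, small_rates):
        """Sum of expected events equals sum of observed events per
        measure-variant-year when the reference rates come from the same
        cohort."""
        defined = small_rates[small_rates["defined"]]
        for (_, _, _), grp in defined.groupby(["year", "measure", "variant"]):
            assert grp["E"].sum() == pytest.approx(grp["O"].sum(), abs=1e-9, rel=1e-9)

    def test_collapse_identity_on_null_cohort(self):
        """Constant stratum rates force adjusted == crude for every OPO."""
        import opometrics as om
        from opometrics.area_profiles import county_quintiles

        cfg = om.make_scenario("null", seed=3, n_counties=60, n_opos=20)
        cohort = om.generate_cohort(cfg)
        q = county_quintiles(cohort.counties.set_index("county_id")["adi"])
        rates = om.compute_all_measures(
            cohort.deaths, cohort.donors, cohort.crosswalk, q, years=cfg.all_years
        )
        piv = rates.pivot_table(
            index=["opo", "year", "measure"], columns="variant", values="rate"
        )
        for variant in ("age", "adi", "age_adi"):
            assert np.allclose(piv[variant], piv["raw"], atol=1e-9)

    def test_zero_potential_opo_flagged_not_ranked(self, tiny_crosswalk):
        deaths = _deaths([(1, 2018, 50, True, True, "a", "a")])
        donors = pd.DataFrame(
            {
                "donor_id": [9], "year": [2018], "age": [50],
                "hospital_county": ["c"], "residence_county": ["c"],
                "organs_transplanted": [2], "kidneys_transplanted": [1],
            }
        )
        quintiles = pd.Series({c: q for c, q in zip("abcdef", [1, 2, 3, 4, 5, 5])})
        rates = compute_all_measures(
            deaths, donors, tiny_crosswalk, quintiles, years=[2018], variants=["raw"]
        )
        opo2 = rates[(rates["opo"] == "OPO2") & (rates["measure"] == "donation")].iloc[0]
        assert not opo2["defined"] and np.isnan(opo2["rate"])


class TestStratumScheme:
    def test_mode_determines_stratum_count(self):
        assert StratumScheme(mode="none").n_strata == 1
        assert StratumScheme(mode="age").n_strata == 6
        assert StratumScheme(mode="adi").n_strata == 5
        assert StratumScheme(mode="age_adi").n_strata == 30

    def test_bins_must_cover_0_to_75(self):
        with pytest.raises(ConfigurationError):
            StratumScheme(mode="age", age_bins=((0, 15), (15, 70)))

    def test_labels_partition_records(self):
        scheme = StratumScheme(mode="age_adi")
        age = np.array([0, 14, 15, 39, 75])
        q = np.array([1, 5, 3, 2, 5])
        labels = scheme.labels(age, q)
        assert labels.tolist() == [0, 4, 1 * 5 + 2, 2 * 5 + 1, 5 * 5 + 4]
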