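"""Incidence estimation, projection, shift scenarios and their simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import meatrisk as m
from meatrisk.mc import mc_standard_error


def make_table(rows):
    """rows: (label, lower, upper, person_years, cases)"""
    return m.StratumTable(tuple(m.Stratum(*r) for r in rows))


class TestEstimateStratumRates:
    def test_direct_division(self):
        t = make_table([("a", 0, None, 1000.0, 10)])
        rates = m.estimate_stratum_rates(t)
        assert rates.rates[0] == 0.01

    def test_pooled_rate_of_published_totals(self, epic_table):
        # 1,329 cases over 2,279,075 person-years
        assert m.pooled_rate(epic_table) == pytest.approx(5.8313e-4, rel=1e-4)
        assert m.pooled_rate(epic_table) == 1329 / 2_279_075

    def test_two_strata_and_pooled(self):
        t = make_table([("a", 0, 40, 500.0, 5), ("b", 40, None, 500.0, 20)])
        rates = m.estimate_stratum_rates(t)
        assert rates.rates == pytest.approx([0.01, 0.04])
        assert m.pooled_rate(t) == pytest.approx(0.025)

    def test_zero_person_years_names_stratum(self):
        t = make_table([("a", 0, 40, 100.0, 1), ("empty", 40, None, 0.0, 0)])
        with pytest.raises(m.ValidationError, match="'empty'"):
            m.estimate_stratum_rates(t)

    def test_annual_risk_convention(self):
        rates = m.IncidenceRates(("a",), np.array([0.02]))
        assert rates.annual_risk[0] == pytest.approx(1 - np.exp(-0.02))


class TestProjectBaselineCases:
    def test_empty_population(self):
        rates = m.IncidenceRates(("a",), np.array([0.01]))
        pop = m.PopulationSpec(0, {"a": 1.0})
        assert m.project_baseline_cases(rates, pop) == 0.0

    def test_single_stratum_closed_form(self):
        rates = m.IncidenceRates(("a",), np.array([5.8313e-4]))
        pop = m.PopulationSpec(1_000_000, {"a": 1.0})
        assert m.project_baseline_cases(rates, pop) == pytest.approx(582.96,
                                                                     abs=0.005)

    def test_two_equal_strata_hand_value(self):
        risks = np.array([0.01, 0.03])
        rates = -np.log1p(-risks)  # invert the annual-risk convention
        inc = m.IncidenceRates(("a", "b"), rates)
        pop = m.PopulationSpec(200, {"a": 0.5, "b": 0.5})
        assert m.project_baseline_cases(inc, pop) == pytest.approx(4.0)

    def test_stratum_mismatch_is_schema_error(self):
        rates = m.IncidenceRates(("a",), np.array([0.01]))
        pop = m.PopulationSpec(10, {"b": 1.0})
        with pytest.raises(m.SchemaError):
            m.project_baseline_cases(rates, pop)


class TestApplyShiftScenario:
    def test_zero_reduction_is_identity(self):
        pop = m.PopulationSpec(100, {"a": 0.9, "b": 0.1})
        scen = m.ShiftScenario(0.0, ("b",), "a")
        assert m.apply_shift_scenario(pop, scen) == pop

    def test_hand_arithmetic_two_sources(self):
        pop = m.PopulationSpec(
            1000, {"low": 0.60, "mid": 0.28, "hi1": 0.10, "hi2": 0.02})
        scen = m.ShiftScenario(0.15, ("hi1", "hi2"), "mid")
        out = m.apply_shift_scenario(pop, scen)
        assert out.stratum_fractions["hi1"] == pytest.approx(0.085)
        assert out.stratum_fractions["hi2"] == pytest.approx(0.017)
        assert out.stratum_fractions["mid"] == pytest.approx(0.28 + 0.018)

    def test_full_reduction_moves_all_mass(self):
        pop = m.PopulationSpec(100, {"a": 0.7, "b": 0.3})
        out = m.apply_shift_scenario(pop, m.ShiftScenario(1.0, ("b",), "a"))
        assert out.stratum_fractions == pytest.approx({"a": 1.0, "b": 0.0})

    @given(fracs=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=6),
           reduction=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mass_conservation_property(self, fracs, reduction):
        labels = [f"s{i}" for i in range(len(fracs))]
        total = sum(fracs)
        pop = m.PopulationSpec(
            12345, dict(zip(labels, [f / total for f in fracs])))
        scen = m.ShiftScenario(reduction, tuple(labels[1:]), labels[0])
        out = m.apply_shift_scenario(pop, scen)
        assert out.total_persons == pop.total_persons
        assert sum(out.stratum_fractions.values()) == pytest.approx(1.0,
                                                                    abs=1e-12)


class TestSimulateCaseReduction:
    def test_null_scenario_paired_draws_have_zero_variance(self,
                                                           two_stratum_setup):
        inc, pop, _ = two_stratum_setup
        scen = m.ShiftScenario(0.0, ("high",), "low")
        mc = m.MCConfig(n_sims=200, seed=5, paired_draws=True)
        res = m.simulate_case_reduction(inc, pop, scen, mc)
        assert (res.mean, res.ci_low, res.ci_high) == (0.0, 0.0, 0.0)

    def test_mean_matches_closed_form_within_three_se(self, two_stratum_setup):
        inc, pop, scen = two_stratum_setup
        mc = m.MCConfig(n_sims=10_000, seed=31)
        draws = m.simulate_case_reduction_draws(inc, pop, scen, mc)
        expected = m.expected_case_reduction(inc, pop, scen)
        # 10% of the high stratum (fraction 0.2) moves down a 0.004 risk gap
        assert expected == pytest.approx(1e6 * 0.2 * 0.1 * 0.004, rel=1e-3)
        assert abs(draws.draws.mean() - expected) <= 3 * mc_standard_error(draws)

    def test_small_shift_interval_can_span_zero(self, two_stratum_setup):
        """With independent draws, a weak scenario's CI straddles zero."""
        inc, pop, _ = two_stratum_setup
        scen = m.ShiftScenario(0.001, ("high",), "low")
        res = m.simulate_case_reduction(
            inc, pop, scen, m.MCConfig(n_sims=2000, seed=8))
        assert res.ci_low < 0 < res.ci_high

    def test_expected_reduction_monotone_in_scenario_size(self,
                                                          two_stratum_setup):
        inc, pop, _ = two_stratum_setup
        reductions = [m.expected_case_reduction(
            inc, pop, m.ShiftScenario(r, ("high",), "low"))
            for r in (0.0, 0.01, 0.05, 0.10, 0.15, 1.0)]
        assert reductions == sorted(reductions)
        assert reductions[0] == 0.0


class TestRRBasedRisk:
    rr = m.RRSpec(rr_per_unit=1.18, reference_intake_g=50,
                  ci_low=1.10, ci_high=1.28)

    @pytest.mark.parametrize("intake_change, multiplier", [
        (50.0, 1.18), (0.0, 1.0), (100.0, 1.3924)])
    def test_dose_response_multipliers(self, intake_change, multiplier):
        base = 0.01
        got = m.rr_based_risk(base, intake_change, self.rr)
        assert got == pytest.approx(base * multiplier, rel=1e-12)

    def test_clamped_to_unit_interval(self):
        assert m.rr_based_risk(0.9, 500.0, self.rr) == 1.0

    def test_baseline_out_of_range_rejected(self):
        with pytest.raises(m.ValidationError):
            m.rr_based_risk(1.5, 0.0, self.rr)
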