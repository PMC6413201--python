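"""Displacement counts, risk calibration and excess-death projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import meatrisk as m
from meatrisk.jobloss import excess_probability_sd
from meatrisk.mc import mc_standard_error
from meatrisk.types import CAUSES


class TestDisplacedWorkers:
    @pytest.mark.parametrize("loss, expected", [
        (0.001, 542.0), (0.0, 0.0), (0.01, 5420.0)])
    def test_published_workforce_products(self, workforce, loss, expected):
        scen = m.EmploymentScenario(loss_fraction=loss)
        assert m.displaced_workers(workforce, scen) == expected


class TestCalibrateCauseRisk:
    def test_allcause_largest_column(self):
        spec = m.calibrate_cause_risk(272.30, (165.53, 378.02), 5420,
                                      "all-cause")
        assert spec.p_mean == pytest.approx(0.0502399, abs=5e-8)
        assert spec.p_q025 == pytest.approx(0.0305406, abs=5e-8)
        assert spec.p_q975 == pytest.approx(0.0697454, abs=5e-8)

    def test_zero_mean_gives_zero_risk(self):
        spec = m.calibrate_cause_risk(0.0, (0.0, 0.0), 100, "x")
        assert spec.p_mean == 0.0

    def test_negative_lower_quantile_allowed(self):
        spec = m.calibrate_cause_risk(21.35, (-91.86, 120.63), 5420, "suicide")
        assert spec.p_q025 == pytest.approx(-0.0169483, abs=5e-8)

    def test_zero_workers_is_calibration_error(self):
        with pytest.raises(m.CalibrationError, match="n_workers"):
            m.calibrate_cause_risk(1.0, (0.0, 2.0), 0, "x")


class TestProjectExcessDeaths:
    def test_allcause_scaled_to_smaller_scenario(self, allcause_risk):
        res = m.project_excess_deaths(allcause_risk, 1626)
        assert res.mean == pytest.approx(81.69, abs=0.02)
        assert res.method == "deterministic"

    def test_zero_workers(self, allcause_risk):
        res = m.project_excess_deaths(allcause_risk, 0)
        assert (res.mean, res.ci_low, res.ci_high) == (0.0, 0.0, 0.0)

    def test_circulatory_scaled(self, reference_grid, workforce):
        specs = m.calibrate_from_reference(reference_grid, workforce, 0.01)
        circ = next(s for s in specs if s.cause == "circulatory")
        res = m.project_excess_deaths(circ, 3252)
        assert res.mean == pytest.approx(52.56, abs=0.02)

    @given(n=st.floats(0, 1e6), k=st.floats(0, 10))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_projection_linear_in_workers(self, allcause_risk, n, k):
        one = m.project_excess_deaths(allcause_risk, n)
        scaled = m.project_excess_deaths(allcause_risk, k * n)
        assert scaled.mean == pytest.approx(k * one.mean, rel=1e-12, abs=1e-9)
        assert scaled.ci_low == pytest.approx(k * one.ci_low, rel=1e-12,
                                              abs=1e-9)
        assert scaled.ci_high == pytest.approx(k * one.ci_high, rel=1e-12,
                                               abs=1e-9)

    def test_cross_column_consistency(self, reference_grid, workforce):
        """Calibrating from any scenario column reproduces every other cell
        to within the propagated printed rounding: a source cell rounded to
        2 decimals carries up to 0.005 of error, which projection scales by
        the scenario ratio, plus 0.005 for the target cell's own rounding.
        From the largest (-1%) column every ratio is <= 1, so all cells
        come back within 0.01 < 0.02 absolute."""
        for source_loss in (0.001, 0.003, 0.006, 0.01):
            specs = m.calibrate_from_reference(reference_grid, workforce,
                                               loss_fraction=source_loss)
            for _, row in reference_grid.iterrows():
                ratio = row["loss_fraction"] / source_loss
                tol = max(0.005 * ratio + 0.005, 0.02)
                spec = next(s for s in specs if s.cause == row["cause"])
                n = m.displaced_workers(
                    workforce, m.EmploymentScenario(row["loss_fraction"]))
                res = m.project_excess_deaths(spec, n)
                assert res.mean == pytest.approx(row["expected_deaths"],
                                                 abs=tol)
                assert res.ci_low == pytest.approx(row["ci_low"], abs=tol)
                assert res.ci_high == pytest.approx(row["ci_high"], abs=tol)
                if source_loss == 0.01:
                    assert res.mean == pytest.approx(row["expected_deaths"],
                                                     abs=0.02)


class TestSimulateExcessDeaths:
    def test_degenerate_spec_collapses_to_binomial(self):
        spec = m.CauseRiskSpec("x", p_mean=0.05, p_q025=0.05, p_q975=0.05)
        mc = m.MCConfig(n_sims=10_000, seed=21)
        res = m.simulate_excess_deaths(spec, 1000, baseline_p=0.0, mc=mc)
        se = np.sqrt(1000 * 0.05 * 0.95 / mc.n_sims)
        assert abs(res.mean - 50.0) <= 3 * se

    def test_worker_level_mean_consistent_with_projection(self, allcause_risk):
        mc = m.MCConfig(n_sims=10_000, seed=3)
        res = m.simulate_excess_deaths(allcause_risk, 5420, mc=mc)
        det = m.project_excess_deaths(allcause_risk, 5420)
        # MC SE from the parameter + binomial variances at these magnitudes
        sd_total = np.sqrt((5420 * excess_probability_sd(allcause_risk))**2
                           + 5420 * 0.08 * 0.92 + 5420 * 0.03 * 0.97)
        assert abs(res.mean - det.mean) <= 3 * sd_total / np.sqrt(mc.n_sims)

    def test_parameter_level_interval_matches_projection(self, allcause_risk):
        mc = m.MCConfig(n_sims=10_000, seed=3)
        res = m.simulate_excess_deaths(allcause_risk, 5420, mc=mc,
                                       worker_level=False)
        det = m.project_excess_deaths(allcause_risk, 5420)
        assert res.ci_low == pytest.approx(det.ci_low, rel=0.05)
        assert res.ci_high == pytest.approx(det.ci_high, rel=0.05)

    def test_interval_widths_equal_across_causes_with_equal_spread(
            self, reference_grid, workforce):
        """Causes sharing the same quantile spread give (near-)identical
        simulated interval widths under a shared seed."""
        specs = m.calibrate_from_reference(reference_grid, workforce, 0.01)
        mc = m.MCConfig(n_sims=4000, seed=17)
        widths = {}
        for s in specs:
            res = m.simulate_excess_deaths(s, 5420, mc=mc, worker_level=False)
            widths[s.cause] = res.ci_high - res.ci_low
        spread = max(widths.values()) - min(widths.values())
        assert spread <= 0.05  # printed spreads differ by at most 0.01 deaths

    def test_negative_mean_excess_gives_negative_mean_deaths(self):
        spec = m.CauseRiskSpec("x", p_mean=-0.01, p_q025=-0.02, p_q975=0.0)
        res = m.simulate_excess_deaths(
            spec, 10_000, baseline_p=0.05, mc=m.MCConfig(n_sims=4000, seed=2))
        assert res.mean < 0

    def test_invalid_baseline_rejected(self, allcause_risk):
        with pytest.raises(m.ValidationError, match="baseline_p"):
            m.simulate_excess_deaths(allcause_risk, 100, baseline_p=1.5)

    def test_all_causes_recognised(self, reference_grid):
        assert set(reference_grid["cause"]) == set(CAUSES)
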