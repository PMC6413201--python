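"""Shared fixtures: bundled cohort/config data and small synthetic setups."""

import numpy as np
import pytest

import meatrisk as m


@pytest.fixture(scope="session")
def epic_table() -> m.StratumTable:
    """Bundled cohort follow-up table (published cases, assumed allocation)."""
    return m.read_config(m.bundled_config_path("epic_table.cfg")).table


@pytest.fixture(scope="session")
def default_bundle() -> m.ConfigBundle:
    return m.read_config(m.bundled_config_path())


@pytest.fixture(scope="session")
def reference_grid():
    """Published displacement mortality grid (5 causes x 4 scenarios)."""
    return m.load_reference_mortality()


@pytest.fixture(scope="session")
def workforce() -> m.WorkforceSpec:
    return m.WorkforceSpec(sector_total=1_000_000, processed_share=0.542)


@pytest.fixture(scope="session")
def allcause_risk(reference_grid, workforce) -> m.CauseRiskSpec:
    """All-cause per-worker risk calibrated from the largest scenario column."""
    specs = m.calibrate_from_reference(reference_grid, workforce,
                                       loss_fraction=0.01)
    return next(s for s in specs if s.cause == "all-cause")


@pytest.fixture
def two_stratum_setup():
    """Small synthetic population for closed-form vs simulation checks.

    Risks chosen so 1 - exp(-rate) inversion is exact: rates are
    -log(1 - risk)."""
    risks = np.array([0.001, 0.005])
    rates = -np.log1p(-risks)
    inc = m.IncidenceRates(labels=("low", "high"), rates=rates)
    pop = m.PopulationSpec(total_persons=1_000_000,
                           stratum_fractions={"low": 0.8, "high": 0.2})
    scen = m.ShiftScenario(reduction_fraction=0.10, source_strata=("high",),
                           destination_stratum="low")
    return inc, pop, scen
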