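"""Excess mortality among processed-meat workers displaced by demand shocks.

The model has three steps:

1. ``displaced_workers``: workforce size x processed-industry share x
   employment-loss fraction.
2. ``calibrate_cause_risk``: turn a published scenario cell (expected
   4-year deaths with 95% CI at a known number of displaced workers) into a
   per-worker excess-death probability with uncertainty quantiles.
3. Projection: deterministic (linear in the number of workers, matching the
   exactly linear scaling of the published scenario grid) or Monte Carlo.

The Monte Carlo projection is second-order: per draw an excess probability
``e`` is sampled from a normal distribution whose mean is ``p_mean`` and
whose sd reproduces the calibrated 2.5%/97.5% quantile spread. With
``worker_level=True`` (default) the draw then simulates individual workers,
``Binomial(n, clamp(baseline_p + e)) - Binomial(n, baseline_p)`` — a
treated-minus-counterfactual difference, so draws and intervals can be
negative. With ``worker_level=False`` the draw is the expected excess
``n * e``: parameter uncertainty only, the component the published
intervals actually carry (their endpoints scale linearly in ``n``, which a
sqrt(n) binomial term would break).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .errors import CalibrationError, ValidationError
from .mc import run_mc, summarize
from .types import (CAUSES, DISPLACEMENT_HORIZON_YEARS, CauseRiskSpec,
                    EmploymentScenario, MCConfig, ScenarioResult,
                    WorkforceSpec)

#: 97.5% standard-normal quantile used to convert CI spread to an sd.
Z975 = 1.959964

#: Default per-worker 4-year baseline (counterfactual) death probability for
#: the worker-level noise term. An assumption, configurable; it only affects
#: the second-order binomial noise, not means or deterministic intervals.
DEFAULT_BASELINE_P = 0.03


def displaced_workers(wf: WorkforceSpec, scen: EmploymentScenario) -> float:
    """Number of workers displaced under an employment-loss scenario."""
    return wf.sector_total * wf.processed_share * scen.loss_fraction


def calibrate_cause_risk(printed_mean: float, printed_ci: tuple[float, float],
                         n_workers: float, cause: str,
                         horizon_years: int = DISPLACEMENT_HORIZON_YEARS,
                         ) -> CauseRiskSpec:
    """Per-worker excess-death probability from a published scenario cell.

    Divides the published expected deaths and CI endpoints by the number of
    displaced workers in that scenario. Lower quantiles may be negative, as
    in the published grid.
    """
    if n_workers <= 0:
        raise CalibrationError("calibrate_cause_risk: n_workers must be > 0")
    lo, hi = printed_ci
    if lo > hi:
        raise CalibrationError("calibrate_cause_risk: CI endpoints out of order")
    return CauseRiskSpec(cause=cause,
                         p_mean=printed_mean / n_workers,
                         p_q025=lo / n_workers,
                         p_q975=hi / n_workers,
                         horizon_years=horizon_years)


def project_excess_deaths(risk: CauseRiskSpec, n_workers: float,
                          scenario_id: str = "") -> ScenarioResult:
    """Deterministic linear projection: n x (p_mean, p_q025, p_q975)."""
    if n_workers < 0:
        raise ValidationError("project_excess_deaths: n_workers must be >= 0")
    return ScenarioResult(
        scenario_id=scenario_id or risk.cause,
        mean=n_workers * risk.p_mean,
        ci_low=n_workers * risk.p_q025,
        ci_high=n_workers * risk.p_q975,
        n_sims_used=0,
        method="deterministic",
    )


def excess_probability_sd(risk: CauseRiskSpec) -> float:
    """Sd of the normal uncertainty distribution implied by the quantiles."""
    return (risk.p_q975 - risk.p_q025) / (2.0 * Z975)


def simulate_excess_deaths(risk: CauseRiskSpec, n_workers: float,
                           baseline_p: float = DEFAULT_BASELINE_P,
                           mc: MCConfig = MCConfig(),
                           worker_level: bool = True,
                           scenario_id: str = "") -> ScenarioResult:
    """Monte Carlo 4-year excess deaths with percentile credibility interval.

    See the module docstring for the two sampling levels. The simulated mean
    is consistent with the deterministic projection (within Monte Carlo
    error); the parameter-level interval converges to the deterministic one,
    while the worker-level interval is wider by the binomial noise of the
    treated and counterfactual cohorts.
    """
    if not 0.0 <= baseline_p <= 1.0:
        raise ValidationError("simulate_excess_deaths: baseline_p must lie in [0, 1]")
    if n_workers < 0:
        raise ValidationError("simulate_excess_deaths: n_workers must be >= 0")
    n = int(round(n_workers))
    sd = excess_probability_sd(risk)

    def sampler(rng: np.random.Generator) -> float:
        e = rng.normal(risk.p_mean, sd) if sd > 0 else risk.p_mean
        if not worker_level:
            return n * e
        p_treated = min(1.0, max(0.0, baseline_p + e))
        return (rng.binomial(n, p_treated) - rng.binomial(n, baseline_p))

    draws = run_mc(sampler, mc)
    return summarize(draws, level=mc.ci_level,
                     scenario_id=scenario_id or risk.cause)


def load_reference_mortality() -> pd.DataFrame:
    """Published 4-year mortality grid for displaced workers (bundled input).

    Columns: ``cause``, ``loss_fraction``, ``expected_deaths``, ``ci_low``,
    ``ci_high`` — five causes by four employment-loss scenarios.
    """
    with resources.files("meatrisk.data").joinpath(
            "displacement_mortality.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, comment="#")
    return df


def calibrate_from_reference(df: pd.DataFrame, wf: WorkforceSpec,
                             loss_fraction: float = 0.01,
                             ) -> list[CauseRiskSpec]:
    """Calibrate every cause from one column of a published mortality grid.

    The default column is the largest scenario (least relative rounding in
    the printed values).
    """
    col = df[np.isclose(df["loss_fraction"], loss_fraction)]
    if col.empty:
        raise CalibrationError(
            f"no rows for loss_fraction={loss_fraction} in the reference grid")
    n = displaced_workers(wf, EmploymentScenario(loss_fraction=loss_fraction))
    specs = []
    for _, row in col.iterrows():
        specs.append(calibrate_cause_risk(
            float(row["expected_deaths"]),
            (float(row["ci_low"]), float(row["ci_high"])),
            n, str(row["cause"])))
    order = {c: i for i, c in enumerate(CAUSES)}
    specs.sort(key=lambda s: order.get(s.cause, len(order)))
    return specs


__all__ = ["Z975", "DEFAULT_BASELINE_P", "displaced_workers",
           "calibrate_cause_risk", "project_excess_deaths",
           "excess_probability_sd", "simulate_excess_deaths",
           "load_reference_mortality", "calibrate_from_reference"]
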