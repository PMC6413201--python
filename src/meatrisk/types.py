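"""Domain types for the two scenario models.

The consumption-shift model works on a cohort follow-up table stratified by
daily processed-meat intake (:class:`StratumTable`), a target population
distributed over the same strata (:class:`PopulationSpec`) and a behavioural
scenario moving a fraction of high-level consumers into a lower stratum
(:class:`ShiftScenario`).

The job-displacement model works on a workforce (:class:`WorkforceSpec`),
employment-loss scenarios (:class:`EmploymentScenario`) and per-worker
4-year excess-death probabilities per cause (:class:`CauseRiskSpec`).

All types validate their invariants eagerly in ``__post_init__`` and raise
:class:`~meatrisk.errors.ValidationError` naming the offending field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import ValidationError

#: Causes of death tracked by the displacement model.
CAUSES = (
    "all-cause",
    "malignant neoplasm",
    "circulatory",
    "suicide",
    "alcohol-related",
)

#: Fixed follow-up horizon (years) of the displacement mortality risks.
DISPLACEMENT_HORIZON_YEARS = 4


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class Stratum:
    """One consumption stratum: intake interval [lower, upper) in g/day.

    ``upper`` is ``None`` for the open-ended top stratum. ``person_years``
    is the exposure accumulated by the cohort in this stratum; ``cases`` the
    incident colorectal-cancer count over the whole follow-up.
    """

    label: str
    lower_g_per_day: float
    upper_g_per_day: Optional[float]
    person_years: float
    cases: int

    def __post_init__(self) -> None:
        _require(self.lower_g_per_day >= 0,
                 f"stratum {self.label!r}: lower_g_per_day must be >= 0")
        if self.upper_g_per_day is not None:
            _require(self.upper_g_per_day > self.lower_g_per_day,
                     f"stratum {self.label!r}: upper bound must exceed lower bound")
        _require(self.person_years >= 0,
                 f"stratum {self.label!r}: person_years must be >= 0")
        _require(isinstance(self.cases, (int,)) and not isinstance(self.cases, bool),
                 f"stratum {self.label!r}: cases must be a non-negative integer")
        _require(self.cases >= 0,
                 f"stratum {self.label!r}: cases must be a non-negative integer")


@dataclass(frozen=True)
class StratumTable:
    """Cohort follow-up by consumption stratum.

    Parameters
    ----------
    strata
        Contiguous, ascending intake strata.
    declared_total_person_years
        Optional externally stated person-year total; when given, the sum of
        stratum person-years must match it.
    cases_cap
        Plausibility cap on each stratum's case count. ``None`` applies the
        default rule ``cases < person_years`` (and ``cases == 0`` where
        ``person_years == 0``).
    """

    strata: tuple[Stratum, ...]
    declared_total_person_years: Optional[float] = None
    cases_cap: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "strata", tuple(self.strata))
        _require(len(self.strata) > 0, "StratumTable: at least one stratum required")
        labels = [s.label for s in self.strata]
        _require(len(set(labels)) == len(labels),
                 "StratumTable: stratum labels must be unique")
        for a, b in zip(self.strata, self.strata[1:]):
            _require(a.upper_g_per_day is not None,
                     f"stratum {a.label!r}: only the top stratum may be unbounded")
            _require(a.lower_g_per_day < b.lower_g_per_day,
                     "StratumTable: strata must be sorted ascending by lower bound")
            _require(math.isclose(a.upper_g_per_day, b.lower_g_per_day, rel_tol=0, abs_tol=1e-9),
                     f"StratumTable: strata {a.label!r} and {b.label!r} are not contiguous")
        if self.declared_total_person_years is not None:
            total = sum(s.person_years for s in self.strata)
            _require(
                math.isclose(total, self.declared_total_person_years,
                             rel_tol=1e-9, abs_tol=1e-6),
                f"StratumTable: person_years sum {total} does not equal the "
                f"declared total {self.declared_total_person_years}",
            )
        for s in self.strata:
            if self.cases_cap is not None:
                plausible = s.cases <= self.cases_cap
            else:
                plausible = s.cases < s.person_years or (s.person_years == 0 and s.cases == 0)
            _require(plausible,
                     f"stratum {s.label!r}: cases {s.cases} exceeds the plausibility cap")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.strata)

    @property
    def total_person_years(self) -> float:
        return float(sum(s.person_years for s in self.strata))

    @property
    def total_cases(self) -> int:
        return int(sum(s.cases for s in self.strata))

    def __getitem__(self, label: str) -> Stratum:
        for s in self.strata:
            if s.label == label:
                return s
        raise KeyError(label)


@dataclass(frozen=True)
class PopulationSpec:
    """Target population to project incidence onto: size and stratum mix."""

    total_persons: float
    stratum_fractions: dict[str, float]

    def __post_init__(self) -> None:
        _require(self.total_persons >= 0,
                 "PopulationSpec: total_persons must be >= 0")
        for label, f in self.stratum_fractions.items():
            _require(f >= 0,
                     f"stratum_fractions[{label!r}] must be >= 0")
        total = sum(self.stratum_fractions.values())
        _require(math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9),
                 f"stratum_fractions must sum to 1 (got {total!r})")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.stratum_fractions)


@dataclass(frozen=True)
class ShiftScenario:
    """Move a fraction of the consumers in ``source_strata`` down to
    ``destination_stratum``.

    The default reading of the study scenarios is that only high-level
    consumers (>40 g/day) change behaviour; ``reduction_fraction`` is the
    share of them that moves.
    """

    reduction_fraction: float
    source_strata: tuple[str, ...]
    destination_stratum: str
    scenario_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_strata", tuple(self.source_strata))
        _require(0.0 <= self.reduction_fraction <= 1.0,
                 "reduction_fraction must lie in [0, 1]")
        _require(len(self.source_strata) > 0,
                 "ShiftScenario: at least one source stratum required")
        _require(self.destination_stratum not in self.source_strata,
                 "destination_stratum must not be one of the source strata")


@dataclass(frozen=True)
class RRSpec:
    """Relative risk per reference intake increment (dose-response anchor)."""

    rr_per_unit: float
    reference_intake_g: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        _require(self.reference_intake_g > 0, "reference_intake_g must be > 0")
        _require(0 < self.ci_low <= self.rr_per_unit <= self.ci_high,
                 "RRSpec requires 0 < ci_low <= rr_per_unit <= ci_high")


@dataclass(frozen=True)
class WorkforceSpec:
    """Meat-sector workforce: total employees and processed-industry share."""

    sector_total: float
    processed_share: float

    def __post_init__(self) -> None:
        _require(self.sector_total >= 0, "sector_total must be >= 0")
        _require(0.0 <= self.processed_share <= 1.0,
                 "processed_share must lie in [0, 1]")


@dataclass(frozen=True)
class EmploymentScenario:
    """Fraction of processed-industry employment lost."""

    loss_fraction: float
    scenario_id: str = ""

    def __post_init__(self) -> None:
        _require(0.0 <= self.loss_fraction <= 1.0,
                 "loss_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CauseRiskSpec:
    """Per-worker excess-death probability over the 4-year horizon.

    ``p_mean`` is the expected excess probability; ``p_q025``/``p_q975`` the
    2.5% and 97.5% quantiles of its uncertainty distribution. The quantiles
    may be negative: an excess is a difference against a counterfactual and
    its interval can span zero.
    """

    cause: str
    p_mean: float
    p_q025: float
    p_q975: float
    horizon_years: int = DISPLACEMENT_HORIZON_YEARS

    def __post_init__(self) -> None:
        _require(self.p_q025 <= self.p_mean <= self.p_q975,
                 f"CauseRiskSpec {self.cause!r}: requires p_q025 <= p_mean <= p_q975")
        _require(self.horizon_years > 0,
                 f"CauseRiskSpec {self.cause!r}: horizon_years must be > 0")


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings: number of draws, seed and interval level."""

    n_sims: int = 10_000
    seed: int = 0
    ci_level: float = 0.95
    paired_draws: bool = False

    def __post_init__(self) -> None:
        _require(self.n_sims >= 1, "MCConfig: n_sims must be >= 1")
        _require(0.0 < self.ci_level < 1.0, "MCConfig: ci_level must lie in (0, 1)")


@dataclass(frozen=True)
class ScenarioResult:
    """Point estimate with credibility interval for one scenario cell."""

    scenario_id: str
    mean: float
    ci_low: float
    ci_high: float
    n_sims_used: int
    method: str  # "deterministic" | "monte_carlo"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        _require(self.method in ("deterministic", "monte_carlo"),
                 "method must be 'deterministic' or 'monte_carlo'")
        _require(self.ci_low <= self.ci_high, "ci_low must not exceed ci_high")


def shifted_fractions(pop: PopulationSpec, scen: ShiftScenario) -> dict[str, float]:
    """Fractions after applying a shift scenario (mass-conserving)."""
    for label in (*scen.source_strata, scen.destination_stratum):
        if label not in pop.stratum_fractions:
            raise ValidationError(f"scenario references unknown stratum {label!r}")
    out = dict(pop.stratum_fractions)
    moved = 0.0
    for label in scen.source_strata:
        delta = out[label] * scen.reduction_fraction
        out[label] -= delta
        moved += delta
    out[scen.destination_stratum] += moved
    return out


__all__ = [
    "CAUSES",
    "DISPLACEMENT_HORIZON_YEARS",
    "Stratum",
    "StratumTable",
    "PopulationSpec",
    "ShiftScenario",
    "RRSpec",
    "WorkforceSpec",
    "EmploymentScenario",
    "CauseRiskSpec",
    "MCConfig",
    "ScenarioResult",
    "shifted_fractions",
]
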