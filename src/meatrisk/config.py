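"""Reading and writing the structured-text configuration and result files.

Configs are YAML with named blocks — ``strata``, ``population``,
``workforce``, ``risks``, ``rr``, ``scenarios``, ``mc`` — all optional at
read time; callers state which blocks they require. Unknown keys warn
rather than fail (forward compatibility); invariant violations fail fast
with the field and rule named. Results are written as CSV or JSON rows that
round-trip to full stored precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError
from .jobloss import calibrate_cause_risk, displaced_workers
from .types import (CauseRiskSpec, EmploymentScenario, MCConfig,
                    PopulationSpec, RRSpec, ScenarioResult, ShiftScenario,
                    Stratum, StratumTable, WorkforceSpec,
                    DISPLACEMENT_HORIZON_YEARS)

_KNOWN_BLOCKS = {"strata", "population", "workforce", "risks", "rr",
                 "scenarios", "mc"}

RESULT_FIELDS = ("scenario_id", "mean", "ci_low", "ci_high",
                 "n_sims_used", "method", "seed")


@dataclass
class ConfigBundle:
    """Everything a run needs, parsed and validated."""

    table: Optional[StratumTable] = None
    population: Optional[PopulationSpec] = None
    workforce: Optional[WorkforceSpec] = None
    baseline_p: float = 0.03
    risks: list[CauseRiskSpec] = field(default_factory=list)
    rr: Optional[RRSpec] = None
    consumption_scenarios: list[ShiftScenario] = field(default_factory=list)
    employment_scenarios: list[EmploymentScenario] = field(default_factory=list)
    mc: MCConfig = field(default_factory=MCConfig)

    def require(self, *blocks: str) -> None:
        """Raise a configuration error naming any absent required block."""
        present = {
            "strata": self.table is not None,
            "population": self.population is not None,
            "workforce": self.workforce is not None,
            "risks": bool(self.risks),
            "rr": self.rr is not None,
            "scenarios": bool(self.consumption_scenarios or self.employment_scenarios),
        }
        for b in blocks:
            if not present.get(b, False):
                raise ConfigurationError(f"configuration is missing the {b!r} block")


def _warn_unknown(mapping: dict, known: set[str], where: str) -> None:
    for key in mapping:
        if key not in known:
            warnings.warn(f"unknown key {key!r} in {where} block ignored",
                          stacklevel=3)


def _as_count(value, name: str) -> int:
    """Validate a non-negative integer count (reals only if integral)."""
    if isinstance(value, bool) or value is None:
        raise ValidationError(f"{name} must be a non-negative integer")
    if isinstance(value, float):
        if not value.is_integer():
            raise ValidationError(f"{name} must be a non-negative integer, got {value}")
        value = int(value)
    if not isinstance(value, int) or value < 0:
        raise ValidationError(f"{name} must be a non-negative integer, got {value!r}")
    return value


def _parse_strata(block: dict) -> StratumTable:
    _warn_unknown(block, {"total_person_years", "allocation_note", "note", "table"},
                  "strata")
    rows = block.get("table")
    if not rows:
        raise ConfigurationError("strata block must contain a 'table' list")
    strata = []
    for row in rows:
        _warn_unknown(row, {"label", "lower", "upper", "person_years", "cases"},
                      "strata.table")
        strata.append(Stratum(
            label=str(row["label"]),
            lower_g_per_day=float(row["lower"]),
            upper_g_per_day=None if row.get("upper") is None else float(row["upper"]),
            person_years=float(row["person_years"]),
            cases=_as_count(row["cases"], f"cases of stratum {row['label']!r}"),
        ))
    declared = block.get("total_person_years")
    return StratumTable(strata=tuple(strata),
                        declared_total_person_years=None if declared is None
                        else float(declared))


def _parse_population(block: dict) -> PopulationSpec:
    _warn_unknown(block, {"total_persons", "stratum_fractions", "note"}, "population")
    return PopulationSpec(
        total_persons=_as_count(block["total_persons"], "total_persons"),
        stratum_fractions={str(k): float(v)
                           for k, v in block["stratum_fractions"].items()},
    )


def _parse_workforce(block: dict) -> tuple[WorkforceSpec, float]:
    _warn_unknown(block, {"sector_total", "processed_share",
                          "baseline_4yr_mortality"}, "workforce")
    wf = WorkforceSpec(sector_total=_as_count(block["sector_total"], "sector_total"),
                       processed_share=float(block["processed_share"]))
    baseline_p = float(block.get("baseline_4yr_mortality", 0.03))
    if not 0.0 <= baseline_p <= 1.0:
        raise ValidationError("baseline_4yr_mortality must lie in [0, 1]")
    return wf, baseline_p


def _parse_risks(rows: Sequence[dict], wf: Optional[WorkforceSpec]) -> list[CauseRiskSpec]:
    specs = []
    for row in rows:
        if "p_mean" in row:
            _warn_unknown(row, {"cause", "p_mean", "p_q025", "p_q975",
                                "horizon_years"}, "risks")
            specs.append(CauseRiskSpec(
                cause=str(row["cause"]),
                p_mean=float(row["p_mean"]),
                p_q025=float(row["p_q025"]),
                p_q975=float(row["p_q975"]),
                horizon_years=int(row.get("horizon_years",
                                          DISPLACEMENT_HORIZON_YEARS)),
            ))
        else:
            _warn_unknown(row, {"cause", "ref_deaths_mean", "ref_ci_low",
                                "ref_ci_high", "ref_loss_fraction",
                                "ref_n_workers", "horizon_years"}, "risks")
            if "ref_n_workers" in row:
                n_ref = float(row["ref_n_workers"])
            else:
                if wf is None:
                    raise ConfigurationError(
                        "risks calibrated via ref_loss_fraction need a "
                        "'workforce' block (or an explicit ref_n_workers)")
                n_ref = displaced_workers(
                    wf, EmploymentScenario(float(row["ref_loss_fraction"])))
            specs.append(calibrate_cause_risk(
                float(row["ref_deaths_mean"]),
                (float(row["ref_ci_low"]), float(row["ref_ci_high"])),
                n_ref, str(row["cause"]),
                horizon_years=int(row.get("horizon_years",
                                          DISPLACEMENT_HORIZON_YEARS))))
    return specs


def _parse_rr(block: dict) -> RRSpec:
    _warn_unknown(block, {"rr_per_unit", "reference_intake_g", "ci_low",
                          "ci_high"}, "rr")
    return RRSpec(rr_per_unit=float(block["rr_per_unit"]),
                  reference_intake_g=float(block["reference_intake_g"]),
                  ci_low=float(block["ci_low"]),
                  ci_high=float(block["ci_high"]))


def _default_sources(table: Optional[StratumTable],
                     threshold_g: float = 40.0) -> tuple[str, ...]:
    """Default shift sources: every stratum with lower bound >= 40 g/day."""
    if table is None:
        raise ConfigurationError(
            "consumption scenarios need explicit source_strata when no "
            "strata block is given")
    return tuple(s.label for s in table.strata if s.lower_g_per_day >= threshold_g)


def _parse_scenarios(block: dict, table: Optional[StratumTable],
                     ) -> tuple[list[ShiftScenario], list[EmploymentScenario]]:
    _warn_unknown(block, {"consumption_reductions", "source_strata",
                          "destination_stratum", "employment_losses"},
                  "scenarios")
    shifts: list[ShiftScenario] = []
    reductions = block.get("consumption_reductions", [])
    if reductions:
        sources = tuple(block["source_strata"]) if "source_strata" in block \
            else _default_sources(table)
        dest = block.get("destination_stratum")
        if dest is None:
            raise ConfigurationError(
                "scenarios block needs 'destination_stratum' when "
                "consumption_reductions are given")
        for r in reductions:
            shifts.append(ShiftScenario(
                reduction_fraction=float(r), source_strata=sources,
                destination_stratum=str(dest),
                scenario_id=f"-{float(r) * 100:g}%"))
    losses = [EmploymentScenario(loss_fraction=float(l),
                                 scenario_id=f"-{float(l) * 100:g}%")
              for l in block.get("employment_losses", [])]
    return shifts, losses


def _parse_mc(block: dict) -> MCConfig:
    _warn_unknown(block, {"n_sims", "seed", "ci_level", "paired_draws"}, "mc")
    return MCConfig(n_sims=int(block.get("n_sims", 10_000)),
                    seed=int(block.get("seed", 0)),
                    ci_level=float(block.get("ci_level", 0.95)),
                    paired_draws=bool(block.get("paired_draws", False)))


def read_config(path) -> ConfigBundle:
    """Parse and validate a config file into a :class:`ConfigBundle`.

    Every block is optional here; use :meth:`ConfigBundle.require` to
    enforce command-specific blocks. Cross-references (scenario strata,
    population strata) are checked against the strata block when present.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} does not contain configuration blocks")
    _warn_unknown(raw, _KNOWN_BLOCKS, "top-level")

    bundle = ConfigBundle()
    if "strata" in raw:
        bundle.table = _parse_strata(raw["strata"])
    if "population" in raw:
        bundle.population = _parse_population(raw["population"])
    if "workforce" in raw:
        bundle.workforce, bundle.baseline_p = _parse_workforce(raw["workforce"])
    if "risks" in raw:
        bundle.risks = _parse_risks(raw["risks"], bundle.workforce)
    if "rr" in raw:
        bundle.rr = _parse_rr(raw["rr"])
    if "mc" in raw:
        bundle.mc = _parse_mc(raw["mc"])
    if "scenarios" in raw:
        bundle.consumption_scenarios, bundle.employment_scenarios = \
            _parse_scenarios(raw["scenarios"], bundle.table)

    _check_cross_references(bundle)
    return bundle


def _check_cross_references(bundle: ConfigBundle) -> None:
    known = set(bundle.table.labels) if bundle.table is not None else None
    if bundle.population is not None and known is not None:
        if set(bundle.population.stratum_fractions) != known:
            raise ConfigurationError(
                "population stratum_fractions do not match the strata block")
    for scen in bundle.consumption_scenarios:
        universe = known if known is not None else (
            set(bundle.population.stratum_fractions)
            if bundle.population is not None else None)
        if universe is None:
            continue
        for label in (*scen.source_strata, scen.destination_stratum):
            if label not in universe:
                raise ConfigurationError(
                    f"scenario references unknown stratum {label!r}")


def bundled_config_path(name: str = "default.cfg") -> Path:
    """Filesystem path of a bundled config (``default.cfg``, ``epic_table.cfg``)."""
    return Path(str(resources.files("meatrisk.data").joinpath(name)))


def write_config(bundle: ConfigBundle, path) -> None:
    """Serialize a bundle back to the block format read by :func:`read_config`."""
    doc: dict = {}
    if bundle.table is not None:
        doc["strata"] = {
            "total_person_years": bundle.table.declared_total_person_years,
            "table": [
                {"label": s.label, "lower": s.lower_g_per_day,
                 "upper": s.upper_g_per_day, "person_years": s.person_years,
                 "cases": s.cases}
                for s in bundle.table.strata],
        }
        if doc["strata"]["total_person_years"] is None:
            del doc["strata"]["total_person_years"]
    if bundle.population is not None:
        doc["population"] = {
            "total_persons": bundle.population.total_persons,
            "stratum_fractions": dict(bundle.population.stratum_fractions),
        }
    if bundle.workforce is not None:
        doc["workforce"] = {
            "sector_total": bundle.workforce.sector_total,
            "processed_share": bundle.workforce.processed_share,
            "baseline_4yr_mortality": bundle.baseline_p,
        }
    if bundle.risks:
        doc["risks"] = [
            {"cause": r.cause, "p_mean": r.p_mean, "p_q025": r.p_q025,
             "p_q975": r.p_q975, "horizon_years": r.horizon_years}
            for r in bundle.risks]
    if bundle.rr is not None:
        doc["rr"] = {"rr_per_unit": bundle.rr.rr_per_unit,
                     "reference_intake_g": bundle.rr.reference_intake_g,
                     "ci_low": bundle.rr.ci_low, "ci_high": bundle.rr.ci_high}
    scen: dict = {}
    if bundle.consumption_scenarios:
        first = bundle.consumption_scenarios[0]
        scen["consumption_reductions"] = [s.reduction_fraction
                                          for s in bundle.consumption_scenarios]
        scen["source_strata"] = list(first.source_strata)
        scen["destination_stratum"] = first.destination_stratum
    if bundle.employment_scenarios:
        scen["employment_losses"] = [s.loss_fraction
                                     for s in bundle.employment_scenarios]
    if scen:
        doc["scenarios"] = scen
    doc["mc"] = {"n_sims": bundle.mc.n_sims, "seed": bundle.mc.seed,
                 "ci_level": bundle.mc.ci_level,
                 "paired_draws": bundle.mc.paired_draws}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False),
                          encoding="utf-8")


def write_results(results: Sequence[ScenarioResult], path,
                  fmt: Optional[str] = None) -> None:
    """Write results as CSV or JSON, one record per scenario, order preserved.

    ``fmt`` defaults to the file suffix. Floats are written with full repr
    precision so re-reading yields identical values.
    """
    results = list(results)
    if not results:
        raise ValidationError("write_results: results must be non-empty")
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    records = [{f: getattr(r, f) for f in RESULT_FIELDS} for r in results]
    if fmt == "csv":
        pd.DataFrame.from_records(records, columns=RESULT_FIELDS).to_csv(
            path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(records, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValidationError(f"write_results: unsupported format {fmt!r}")


def read_results(path, fmt: Optional[str] = None) -> list[ScenarioResult]:
    """Re-read a results file written by :func:`write_results`."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.read_csv(path)
        records = df.to_dict(orient="records")
    elif fmt == "json":
        records = json.loads(path.read_text(encoding="utf-8"))
    else:
        raise ValidationError(f"read_results: unsupported format {fmt!r}")
    out = []
    for rec in records:
        seed = rec.get("seed")
        if seed is not None and not (isinstance(seed, float) and pd.isna(seed)):
            seed = int(seed)
        else:
            seed = None
        out.append(ScenarioResult(
            scenario_id=str(rec["scenario_id"]), mean=float(rec["mean"]),
            ci_low=float(rec["ci_low"]), ci_high=float(rec["ci_high"]),
            n_sims_used=int(rec["n_sims_used"]), method=str(rec["method"]),
            seed=seed))
    return out


__all__ = ["ConfigBundle", "read_config", "write_config", "write_results",
           "read_results", "bundled_config_path", "RESULT_FIELDS"]
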