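"""Seeded Monte Carlo driver and credibility-interval computation.

Both scenario models run through :func:`run_mc`, which hands every draw its
own independent random substream (spawned from a single ``SeedSequence``),
so results are bit-reproducible under a fixed seed and insensitive to the
total number of draws requested. Credibility intervals are empirical
percentile intervals of the draws, using the "linear" sample-quantile
convention (linear interpolation between order statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import MeatriskError, ValidationError
from .types import MCConfig, ScenarioResult


@dataclass(frozen=True)
class DrawSet:
    """Ordered Monte Carlo draws plus the seed that generated them."""

    draws: np.ndarray
    seed: int
    n_sims: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "draws", np.asarray(self.draws, dtype=float))
        if self.draws.ndim != 1 or self.draws.size != self.n_sims:
            raise ValidationError(
                f"DrawSet: expected {self.n_sims} draws, got shape {self.draws.shape}")


class SamplerError(MeatriskError):
    """A user-supplied sampler raised; carries the failing draw index."""

    def __init__(self, index: int, original: BaseException):
        self.index = index
        super().__init__(f"sampler failed at draw index {index}: {original!r}")


def run_mc(sampler: Callable[[np.random.Generator], float], mc: MCConfig) -> DrawSet:
    """Run ``mc.n_sims`` draws of ``sampler``, one substream per draw index.

    ``sampler`` receives a fresh :class:`numpy.random.Generator` per draw and
    returns one real number. Regenerating with the same seed and sampler
    yields an identical sequence.
    """
    children = np.random.SeedSequence(mc.seed).spawn(mc.n_sims)
    draws = np.empty(mc.n_sims, dtype=float)
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        try:
            draws[i] = float(sampler(rng))
        except Exception as exc:  # noqa: BLE001 - contract: propagate with index
            raise SamplerError(i, exc) from exc
    return DrawSet(draws=draws, seed=mc.seed, n_sims=mc.n_sims)


def _as_draws(d) -> np.ndarray:
    arr = d.draws if isinstance(d, DrawSet) else np.asarray(d, dtype=float)
    if arr.size == 0:
        raise ValidationError("percentile_ci: draws are empty")
    return arr


def percentile_ci(d, level: float) -> tuple[float, float]:
    """Equal-tailed empirical percentile interval of the draws.

    Quantiles at ``(1-level)/2`` and ``1-(1-level)/2`` with linear
    interpolation between order statistics.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError("percentile_ci: level must lie in (0, 1)")
    arr = _as_draws(d)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(arr, [alpha, 1.0 - alpha], method="linear")
    return float(low), float(high)


def mc_standard_error(d) -> float:
    """Monte Carlo standard error of the mean: sd(draws)/sqrt(n)."""
    arr = _as_draws(d)
    if arr.size == 1:
        return 0.0
    return float(arr.std(ddof=1) / np.sqrt(arr.size))


def summarize(d: DrawSet, level: float = 0.95, scenario_id: str = "") -> ScenarioResult:
    """Mean of draws plus percentile credibility interval."""
    low, high = percentile_ci(d, level)
    return ScenarioResult(
        scenario_id=scenario_id,
        mean=float(_as_draws(d).mean()),
        ci_low=low,
        ci_high=high,
        n_sims_used=d.n_sims,
        method="monte_carlo",
        seed=d.seed,
    )


__all__ = ["DrawSet", "SamplerError", "run_mc", "percentile_ci",
           "mc_standard_error", "summarize"]
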