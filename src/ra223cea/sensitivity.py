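"""One-way (tornado) and probabilistic sensitivity analysis, and CEAC.

OWSA re-evaluates both arms with one parameter at a time pushed to its lower
and upper bound (the ranges attached to each parameter in the configuration,
plus the structural discount-rate and time-horizon scenarios), ranking
parameters by the absolute ICER spread.

PSA samples every ranged parameter independently — gamma distributions for
resource use and unit costs, beta for rates, proportions and utilities —
with moments matched to (base value, range-implied standard error), where
``se = (upper - lower) / (2 * 1.96)`` treats the range as a 95% interval.
Survival-curve parameters are not sampled: no uncertainty ranges are
published for them, so the base-case PSA holds the curves fixed (the traces
are therefore computed once per arm and reused across draws).
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import build_trace
from .config import ARM_BSC, ARM_RADIUM, ModelConfig, override
from .economics import CEAResult, compute_icer, evaluate_arm

__all__ = [
    "TornadoEntry",
    "PSASample",
    "MatchedDistribution",
    "run_owsa",
    "moment_match",
    "run_psa",
    "ceac",
    "evaluate_base",
]


def evaluate_base(config: ModelConfig) -> CEAResult:
    """Both arms under one configuration, as a CEAResult."""
    return compute_icer(
        evaluate_arm(config, ARM_RADIUM), evaluate_arm(config, ARM_BSC)
    )


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    param_id: str
    lower: float
    upper: float
    icer_at_lower: float
    icer_at_upper: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_upper - self.icer_at_lower)


def _numeric_icer(result: CEAResult) -> float:
    icer = result.icer
    return icer if isinstance(icer, float) else math.nan


def run_owsa(config: ModelConfig) -> list[TornadoEntry]:
    """Tornado entries for every ranged parameter, sorted by spread (desc).

    Structural scenarios (``owsa_structural`` section: discount rate,
    horizon) are varied alongside the tabulated parameter ranges.  Parameters
    whose range violates their own bounds are skipped with a warning.
    """
    entries: list[TornadoEntry] = []
    jobs: list[tuple[str, float, float]] = []
    for spec in config.iter_params():
        if spec.has_range and spec.lower < spec.upper:
            jobs.append((spec.path, spec.lower, spec.upper))
    for pid, rng in config.values.get("owsa_structural", {}).items():
        jobs.append((pid, float(rng[0]), float(rng[1])))

    for pid, lo, hi in jobs:
        try:
            icer_lo = _numeric_icer(evaluate_base(override(config, pid, lo)))
            icer_hi = _numeric_icer(evaluate_base(override(config, pid, hi)))
        except (ValueError, KeyError) as err:
            warnings.warn(f"OWSA skipped {pid}: {err}")
            continue
        entries.append(
            TornadoEntry(
                param_id=pid,
                lower=lo,
                upper=hi,
                icer_at_lower=icer_lo,
                icer_at_upper=icer_hi,
            )
        )
    entries.sort(key=lambda e: (-(e.spread if math.isfinite(e.spread) else -1.0)))
    return entries


# ---------------------------------------------------------------------------
# moment matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchedDistribution:
    """A gamma or beta law moment-matched to (mean, range-implied se)."""

    kind: str  # "gamma", "beta" or "point"
    mean: float
    se: float
    params: tuple[float, ...] = ()

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "point":
            return self.mean if size is None else np.full(size, self.mean)
        if self.kind == "gamma":
            shape, rate = self.params
            return rng.gamma(shape, 1.0 / rate, size)
        alpha, beta = self.params
        return rng.beta(alpha, beta, size)


def moment_match(
    mean: float, lower: float, upper: float, kind: str
) -> MatchedDistribution:
    """Gamma/beta parameters with the requested mean and range-implied se.

    ``se = (upper - lower) / (2 * 1.96)``.  Gamma: ``shape = mean^2/se^2``,
    ``rate = mean/se^2``.  Beta: ``alpha = mean * (mean(1-mean)/se^2 - 1)``
    and ``beta = (1-mean) * (same)``.  A zero se yields a flagged point mass;
    infeasible beta moments (``se^2 >= mean(1-mean)``) raise.
    """
    if kind not in ("gamma", "beta"):
        raise ValueError(f"kind must be 'gamma' or 'beta', got {kind!r}")
    if not lower <= mean <= upper:
        raise ValueError(f"need lower <= mean <= upper, got ({lower}, {mean}, {upper})")
    se = (upper - lower) / (2.0 * 1.96)
    if se == 0.0:
        return MatchedDistribution(kind="point", mean=mean, se=0.0)
    if kind == "gamma":
        if mean <= 0.0:
            raise ValueError("gamma moment matching needs a positive mean")
        shape = mean**2 / se**2
        rate = mean / se**2
        return MatchedDistribution(kind="gamma", mean=mean, se=se, params=(shape, rate))
    if not (0.0 <= lower and upper <= 1.0):
        raise ValueError("beta moment matching needs values in [0, 1]")
    if mean in (0.0, 1.0) or se**2 >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible beta moments: mean {mean}, se {se} "
            f"(need se^2 < mean(1-mean))"
        )
    nu = mean * (1.0 - mean) / se**2 - 1.0
    return MatchedDistribution(
        kind="beta", mean=mean, se=se, params=(mean * nu, (1.0 - mean) * nu)
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSASample:
    draw: int
    params: dict[str, float] = field(repr=False)
    cost_reference: float
    qalys_reference: float
    cost_comparator: float
    qalys_comparator: float

    @property
    def delta_cost(self) -> float:
        return self.cost_reference - self.cost_comparator

    @property
    def delta_qalys(self) -> float:
        return self.qalys_reference - self.qalys_comparator


def _bulk_override(config: ModelConfig, updates: dict[str, float]) -> ModelConfig:
    values = copy.deepcopy(dict(config.values))
    for path, value in updates.items():
        node = values
        *head, leaf = path.split(".")
        for part in head:
            node = node[part]
        node[leaf] = float(value)
    return ModelConfig(
        values=values, owsa_ranges=config.owsa_ranges, calibrated=config.calibrated
    )


def run_psa(config: ModelConfig, n_draws: int, seed: int) -> list[PSASample]:
    """``n_draws`` independent parameter draws, both arms re-evaluated per draw.

    Infeasible moment matching on any parameter fails at setup.  Identical
    seeds give identical samples (``numpy.random.default_rng`` PCG64).
    """
    if n_draws < 1:
        raise ValueError("need at least one draw")
    samplers: list[tuple[str, MatchedDistribution]] = []
    for spec in config.iter_params():
        if not spec.has_range:
            continue
        samplers.append(
            (spec.path, moment_match(spec.value, spec.lower, spec.upper, spec.kind))
        )

    # curves are never sampled: traces are fixed across draws
    traces = {
        arm: build_trace(
            config.curve("OS", arm),
            config.curve("PFS", arm),
            config.curve("SSE", arm),
            horizon_weeks=config.horizon_weeks,
            cycle_weeks=config.cycle_weeks,
        )
        for arm in (ARM_RADIUM, ARM_BSC)
    }

    rng = np.random.default_rng(seed)
    samples: list[PSASample] = []
    for i in range(n_draws):
        drawn = {path: float(dist.sample(rng)) for path, dist in samplers}
        cfg_i = _bulk_override(config, drawn)
        ref = evaluate_arm(cfg_i, ARM_RADIUM, trace=traces[ARM_RADIUM])
        comp = evaluate_arm(cfg_i, ARM_BSC, trace=traces[ARM_BSC])
        samples.append(
            PSASample(
                draw=i,
                params=drawn,
                cost_reference=ref.total_cost,
                qalys_reference=ref.qalys,
                cost_comparator=comp.total_cost,
                qalys_comparator=comp.qalys,
            )
        )
    return samples


def ceac(
    samples: Sequence[PSASample], wtp_grid: Sequence[float]
) -> list[tuple[float, float]]:
    """Probability of cost-effectiveness at each willingness-to-pay value.

    For each threshold the fraction of draws with strictly positive net
    monetary benefit (``wtp * dQALY - dCost > 0``); ties count as not
    cost-effective.
    """
    if len(samples) == 0:
        raise ValueError("need at least one PSA sample")
    de = np.array([s.delta_qalys for s in samples])
    dc = np.array([s.delta_cost for s in samples])
    out = []
    for wtp in wtp_grid:
        frac = float(np.mean(wtp * de - dc > 0.0))
        out.append((float(wtp), frac))
    return out
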