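"""Weekly cohort trace over the five mCRPC health states.

The model follows a simulated cohort through five mutually exclusive states —
progression-free without SSE, progression-free with SSE, progressed without
SSE, progressed with SSE, and dead — starting everyone progression-free and
SSE-free.  Because only the three marginal endpoint curves (overall survival,
progression-free survival, time to first SSE) are available, occupancy is
derived by the partitioned-survival ("area under the curve") construction,
with min() guards enforcing the logical nesting that neither progression-free
nor SSE-free status can outlive overall survival:

    alive          = S_OS(t)
    PF & alive     = min(S_PFS, S_OS)(t)
    noSSE & alive  = min(S_SSE, S_OS)(t)
    PF_noSSE       = min(S_PFS, S_SSE, S_OS)(t)

and the remaining states by subtraction.

Event *incidence* streams (new deaths, new progressions, new first SSEs per
cycle) are per-cycle hazard flows over the at-risk occupancy, i.e. the
cumulative incidences implied by independent event clocks:

    deaths_k       = S_OS(t_{k-1}) - S_OS(t_k)
    progressions_k = max(0, -d[PF&alive] - deaths_k * (PF&alive)/alive)
    first_sse_k    = S_OS(t_{k-1}) * S_SSE(t_{k-1}) * h_SSE(k)

where ``h_SSE(k)`` is the conditional per-cycle probability from the SSE
curve.  Progression events are PFS-curve events net of the deaths
attributable to the progression-free pool, so that a patient dying without
progressing is never counted as a progression.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import SurvivalCurve, survival_at

__all__ = [
    "HealthState",
    "CohortTrace",
    "TraceWarning",
    "build_trace",
    "death_incidence",
    "first_sse_incidence",
    "progression_incidence",
]


class HealthState(enum.Enum):
    PF_NO_SSE = "pf_no_sse"
    PF_SSE = "pf_sse"
    PROG_NO_SSE = "prog_no_sse"
    PROG_SSE = "prog_sse"
    DEAD = "dead"


class TraceWarning(UserWarning):
    """Signals curve-crossing artefacts clipped during trace construction."""


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy and event incidence.

    Occupancy arrays have length ``n_cycles + 1`` (values at cycle
    boundaries, week ``k * cycle_weeks``); incidence arrays have length
    ``n_cycles`` and give the fraction of the initial cohort experiencing the
    event during cycle ``k`` (i.e. between boundaries ``k`` and ``k+1``).
    """

    weeks: np.ndarray
    pf_no_sse: np.ndarray
    pf_sse: np.ndarray
    prog_no_sse: np.ndarray
    prog_sse: np.ndarray
    dead: np.ndarray
    new_deaths: np.ndarray
    new_progressions: np.ndarray
    new_first_sse: np.ndarray
    cycle_weeks: float = 1.0

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.dead

    @property
    def pf(self) -> np.ndarray:
        return self.pf_no_sse + self.pf_sse

    @property
    def progressed(self) -> np.ndarray:
        return self.prog_no_sse + self.prog_sse

    @property
    def n_cycles(self) -> int:
        return len(self.weeks) - 1

    def occupancy(self, state: HealthState) -> np.ndarray:
        return getattr(self, state.value)

    def occupancy_matrix(self) -> np.ndarray:
        """(n_cycles+1, 5) matrix in HealthState order."""
        return np.column_stack(
            [self.pf_no_sse, self.pf_sse, self.prog_no_sse, self.prog_sse, self.dead]
        )

    def to_frame(self) -> pd.DataFrame:
        n = self.n_cycles
        pad = lambda a: np.concatenate([[0.0], a])  # incidences start at cycle 1
        return pd.DataFrame(
            {
                "cycle": np.arange(n + 1),
                "week": self.weeks,
                "pf_no_sse": self.pf_no_sse,
                "pf_sse": self.pf_sse,
                "prog_no_sse": self.prog_no_sse,
                "prog_sse": self.prog_sse,
                "dead": self.dead,
                "new_deaths": pad(self.new_deaths),
                "new_progressions": pad(self.new_progressions),
                "new_first_sse": pad(self.new_first_sse),
            }
        )


def build_trace(
    os_curve: SurvivalCurve,
    pfs_curve: SurvivalCurve,
    sse_curve: SurvivalCurve,
    horizon_weeks: float,
    cycle_weeks: float = 1.0,
) -> CohortTrace:
    """Build the five-state cohort trace from the three endpoint curves.

    ``horizon_weeks`` must be an integer multiple of ``cycle_weeks``.  A
    negative computed occupancy beyond -1e-6 (a severe curve-crossing
    pathology) raises; milder crossings are clipped with a warning.
    """
    n = horizon_weeks / cycle_weeks
    if abs(n - round(n)) > 1e-9:
        raise ValueError("horizon must be an integer multiple of the cycle length")
    n = int(round(n))
    weeks = np.arange(n + 1) * cycle_weeks

    s_os = survival_at(os_curve, weeks)
    s_pfs = survival_at(pfs_curve, weeks)
    s_sse = survival_at(sse_curve, weeks)

    alive = s_os
    pf_alive = np.minimum(s_pfs, s_os)
    nosse_alive = np.minimum(s_sse, s_os)
    pf_no_sse = np.minimum(pf_alive, nosse_alive)
    pf_sse = pf_alive - pf_no_sse
    prog_no_sse = nosse_alive - pf_no_sse
    prog_sse = alive - pf_no_sse - pf_sse - prog_no_sse
    dead = 1.0 - alive

    worst = min(prog_sse.min(), pf_sse.min(), prog_no_sse.min(), 0.0)
    if worst < -1e-6:
        raise ValueError(
            f"curve-crossing pathology: occupancy {worst:.3e} at cycle "
            f"{int(np.argmin(prog_sse))}"
        )
    if worst < -1e-9:
        warnings.warn(
            f"clipped slightly negative occupancy ({worst:.3e})", TraceWarning
        )
    pf_sse = np.clip(pf_sse, 0.0, 1.0)
    prog_no_sse = np.clip(prog_no_sse, 0.0, 1.0)
    prog_sse = np.clip(prog_sse, 0.0, 1.0)

    new_deaths = np.diff(dead)
    # PFS-curve events net of deaths attributable to the progression-free pool
    with np.errstate(divide="ignore", invalid="ignore"):
        pf_share = np.where(alive[:-1] > 0.0, pf_alive[:-1] / alive[:-1], 0.0)
    new_progressions = np.clip(-np.diff(pf_alive) - new_deaths * pf_share, 0.0, None)
    # first-SSE flow: marginal SSE hazard applied to the independent at-risk pool
    with np.errstate(divide="ignore", invalid="ignore"):
        sse_hazard = np.where(
            s_sse[:-1] > 0.0, 1.0 - s_sse[1:] / np.where(s_sse[:-1] > 0, s_sse[:-1], 1.0), 0.0
        )
    new_first_sse = s_os[:-1] * s_sse[:-1] * sse_hazard

    return CohortTrace(
        weeks=weeks,
        pf_no_sse=pf_no_sse,
        pf_sse=pf_sse,
        prog_no_sse=prog_no_sse,
        prog_sse=prog_sse,
        dead=dead,
        new_deaths=new_deaths,
        new_progressions=new_progressions,
        new_first_sse=new_first_sse,
        cycle_weeks=cycle_weeks,
    )


def death_incidence(trace: CohortTrace) -> np.ndarray:
    """Per-cycle fraction of the cohort dying; sums to ``1 - S_OS(horizon)``."""
    return trace.new_deaths


def progression_incidence(trace: CohortTrace) -> np.ndarray:
    """Per-cycle fraction progressing while alive (feeds second-line costs)."""
    return trace.new_progressions


def first_sse_incidence(trace: CohortTrace) -> np.ndarray:
    """Per-cycle fraction experiencing a first SSE while alive."""
    return trace.new_first_sse
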