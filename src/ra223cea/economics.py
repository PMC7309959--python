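"""Discounted outcome and cost accrual over a cohort trace, and ICER logic.

Accrual conventions (no half-cycle correction by default, matching a weekly
Excel-style cohort model):

* state-occupancy quantities (life-years, QALYs, management and facility
  costs) count membership at the *start* of each cycle and discount at the
  cycle-start time;
* event-driven quantities (end-of-life, second-line, SSE treatment costs)
  discount at the *end* of the cycle in which the event occurs;
* radium-223 drug and administration costs are charged undiscounted at the
  scheduled injections (the whole course falls inside the first 6 months,
  where discounting is negligible).

Life-years are reported undiscounted by default (QALYs and costs are always
discounted); a config switch (``discount_life_years``) reports discounted
life-years instead.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .cohort import CohortTrace, build_trace
from .config import ARM_BSC, ARMS, ModelConfig

__all__ = [
    "CostBreakdown",
    "ArmResult",
    "CEAResult",
    "discount_factor",
    "accrue_life_years",
    "accrue_qalys",
    "drug_and_admin_cost",
    "management_cost",
    "facility_costs",
    "ae_cost",
    "sse_event_cost",
    "terminal_and_secondline_costs",
    "evaluate_arm",
    "compute_icer",
    "net_monetary_benefit",
]

_STATE_OCC = {
    "pf_no_sse": "pf_no_sse",
    "pf_sse": "pf_sse",
    "prog_no_sse": "prog_no_sse",
    "prog_sse": "prog_sse",
}


def discount_factor(t_weeks, annual_rate: float):
    """``(1 + r)^(-t/52)`` for scalar or array ``t`` in weeks."""
    t = np.asarray(t_weeks, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    out = (1.0 + annual_rate) ** (-t / 52.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted per-patient costs in the nine reporting categories."""

    drug: float = 0.0
    administration: float = 0.0
    patient_management: float = 0.0
    hospitalization: float = 0.0
    day_care: float = 0.0
    physician_visits: float = 0.0
    second_line: float = 0.0
    end_of_life: float = 0.0
    sse: float = 0.0
    adverse_events: float = 0.0

    @property
    def total(self) -> float:
        return float(sum(getattr(self, f.name) for f in fields(self)))

    def as_dict(self) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["total"] = self.total
        return d


@dataclass(frozen=True)
class ArmResult:
    arm: str
    life_years: float
    life_years_discounted: float
    qalys: float
    costs: CostBreakdown

    @property
    def total_cost(self) -> float:
        return self.costs.total


@dataclass(frozen=True)
class CEAResult:
    """Incremental cost-effectiveness of a reference arm vs a comparator."""

    reference: ArmResult
    comparator: ArmResult

    @property
    def delta_cost(self) -> float:
        return self.reference.total_cost - self.comparator.total_cost

    @property
    def delta_qalys(self) -> float:
        return self.reference.qalys - self.comparator.qalys

    @property
    def delta_life_years(self) -> float:
        return self.reference.life_years - self.comparator.life_years

    @property
    def icer(self) -> float | str:
        """EUR per QALY from unrounded values, or a dominance label."""
        dc, de = self.delta_cost, self.delta_qalys
        if de == 0.0:
            return "undefined"
        if dc < 0.0 and de > 0.0:
            return "dominant"
        if dc > 0.0 and de < 0.0:
            return "dominated"
        return dc / de


# ---------------------------------------------------------------------------
# outcome accrual
# ---------------------------------------------------------------------------


def _cycle_start_weights(trace: CohortTrace, rate: float, half_cycle: bool):
    """Discount weights and occupancy selector for per-cycle accrual."""
    d = discount_factor(trace.weeks[:-1], rate)
    if half_cycle:
        mid = 0.5 * (trace.weeks[:-1] + trace.weeks[1:])
        d = discount_factor(mid, rate)
    return d


def _occ(trace: CohortTrace, name: str, half_cycle: bool) -> np.ndarray:
    a = getattr(trace, name)
    return 0.5 * (a[:-1] + a[1:]) if half_cycle else a[:-1]


def accrue_life_years(
    trace: CohortTrace, rate: float = 0.0, half_cycle: bool = False
) -> float:
    """Discounted years alive over the trace."""
    d = _cycle_start_weights(trace, rate, half_cycle)
    return float(np.sum(_occ(trace, "alive", half_cycle) * d)) * trace.cycle_weeks / 52.0


def accrue_qalys(
    trace: CohortTrace,
    utilities: dict[str, float],
    rate: float,
    half_cycle: bool = False,
    pf_no_sse_late: float | None = None,
    window_weeks: float | None = None,
) -> float:
    """Sum of occupancy x state utility x cycle length x discount.

    ``utilities`` maps the four alive-state keys to values in [0, 1] (dead is
    0 by construction).  If ``window_weeks`` is given, the PF-noSSE state uses
    ``utilities['pf_no_sse']`` inside the window and ``pf_no_sse_late``
    afterwards.
    """
    missing = [s for s in _STATE_OCC if s not in utilities]
    if missing:
        raise ValueError(f"missing utilities for occupied states: {missing}")
    bad = {s: u for s, u in utilities.items() if not 0.0 <= u <= 1.0}
    if bad:
        raise ValueError(f"utilities outside [0, 1]: {bad}")
    d = _cycle_start_weights(trace, rate, half_cycle)
    total = 0.0
    for state in _STATE_OCC:
        occ = _occ(trace, state, half_cycle)
        u = np.full(len(occ), utilities[state])
        if state == "pf_no_sse" and window_weeks is not None:
            late = utilities["pf_no_sse"] if pf_no_sse_late is None else pf_no_sse_late
            u = np.where(trace.weeks[:-1] < window_weeks, utilities[state], late)
        total += float(np.sum(occ * u * d))
    return total * trace.cycle_weeks / 52.0


# ---------------------------------------------------------------------------
# cost accrual
# ---------------------------------------------------------------------------


def drug_and_admin_cost(config: ModelConfig, arm: str) -> tuple[float, float]:
    """(drug, administration) cost; zero for the BSC arm."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if arm == ARM_BSC:
        return 0.0, 0.0
    n = config["mean_injections"]
    return (
        n * config["drug_price_per_injection"],
        n * config["administration_cost_per_injection"],
    )


def management_cost(
    trace: CohortTrace, config: ModelConfig, rate: float, half_cycle: bool = False
) -> float:
    """Routine-monitoring plus other supportive-care cost, by disease phase."""
    weekly = {}
    for phase in ("stable", "progressed"):
        freq = config[f"management_frequencies.{phase}"]
        costs = config["management_unit_costs"]
        weekly[phase] = sum(freq[res] * costs[res] for res in freq)
        weekly[phase] += config[f"management_other_weekly_cost.{phase}"]
    d = _cycle_start_weights(trace, rate, half_cycle)
    pf = _occ(trace, "pf", half_cycle)
    prog = _occ(trace, "progressed", half_cycle)
    per_week = pf * weekly["stable"] + prog * weekly["progressed"]
    return float(np.sum(per_week * d)) * trace.cycle_weeks


def facility_costs(
    trace: CohortTrace,
    config: ModelConfig,
    rate: float,
    arm: str,
    half_cycle: bool = False,
) -> tuple[float, float, float]:
    """(hospitalization, day-care, physician-visit) costs from annual use rates."""
    cells = {
        ("stable", "no_sse"): "pf_no_sse",
        ("stable", "sse"): "pf_sse",
        ("progressed", "no_sse"): "prog_no_sse",
        ("progressed", "sse"): "prog_sse",
    }
    unit = {
        "hospitalization_days": config["unit_costs.hospitalization_day"],
        "daycare_days": config["unit_costs.daycare_day"],
        "physician_visits": config["unit_costs.physician_visit"],
    }
    d = _cycle_start_weights(trace, rate, half_cycle)
    out = []
    for resource, cost in unit.items():
        total = 0.0
        for (phase, sse), state in cells.items():
            annual = config[f"facility_use.{resource}.{phase}.{sse}.{arm}"]
            occ = _occ(trace, state, half_cycle)
            total += float(np.sum(occ * d)) * (annual / 52.0) * cost * trace.cycle_weeks
        out.append(total)
    return tuple(out)


def ae_cost(
    trace: CohortTrace,
    config: ModelConfig,
    rate: float,
    arm: str,
    half_cycle: bool = False,
) -> float:
    """Adverse-event treatment cost over the on-treatment window.

    Weekly AE rates come from on-treatment safety data, so they are applied
    to the progression-free (still on treatment) occupancy inside the
    treatment window.  Each event costs
    ``p_hosp * days * hospital_day + (1 - p_hosp) * outpatient``.
    """
    rates = config["ae_weekly_rates"]
    p_hosp = config["ae_hospitalization_proportion"]
    outpatient = config["ae_outpatient_cost"]
    mismatch = set(rates).symmetric_difference(p_hosp) | set(
        rates
    ).symmetric_difference(outpatient)
    if mismatch:
        raise ValueError(f"adverse-event tables misaligned on: {sorted(mismatch)}")
    hosp_day = config["unit_costs.hospitalization_day"]
    days = config["ae_hospital_days_per_event"]
    weekly = sum(
        rates[name][arm]
        * (p_hosp[name] * days * hosp_day + (1.0 - p_hosp[name]) * outpatient[name])
        for name in rates
    )
    window = config["treatment_window_weeks"]
    d = _cycle_start_weights(trace, rate, half_cycle)
    occ = _occ(trace, "pf", half_cycle)
    in_window = trace.weeks[:-1] < window
    return float(np.sum(occ * d * in_window)) * weekly * trace.cycle_weeks


def sse_event_cost(
    first_sse: np.ndarray, trace: CohortTrace, config: ModelConfig, rate: float, arm: str
) -> float:
    """Cost of first symptomatic skeletal events, by type mix."""
    dist = config["sse_type_distribution"]
    unit = config["sse_type_unit_cost"]
    mean_cost = sum(dist[t][arm] * unit[t] for t in dist)
    d = discount_factor(trace.weeks[1:], rate)
    return float(np.sum(first_sse * d)) * mean_cost


def terminal_and_secondline_costs(
    trace: CohortTrace, config: ModelConfig, rate: float, arm: str
) -> tuple[float, float]:
    """(end-of-life, second-line) costs from the incidence streams."""
    d = discount_factor(trace.weeks[1:], rate)
    eol = float(np.sum(trace.new_deaths * d)) * config["unit_costs.end_of_life"]
    second = (
        float(np.sum(trace.new_progressions * d))
        * config[f"second_line.proportion.{arm}"]
        * config["second_line.cost_per_patient"]
    )
    return eol, second


# ---------------------------------------------------------------------------
# arm evaluation and incremental statistics
# ---------------------------------------------------------------------------


def evaluate_arm(
    config: ModelConfig, arm: str, trace: CohortTrace | None = None
) -> ArmResult:
    """Run the full accrual pipeline for one arm (deterministic)."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if trace is None:
        trace = build_trace(
            config.curve("OS", arm),
            config.curve("PFS", arm),
            config.curve("SSE", arm),
            horizon_weeks=config.horizon_weeks,
            cycle_weeks=config.cycle_weeks,
        )
    rate = config["discount_rate_annual"]
    half = bool(config.values.get("half_cycle_correction", False))

    utilities = {s: config[f"utilities.{s}.{arm}"] for s in _STATE_OCC}
    window = config.values.get("utility_treatment_window_weeks")
    qalys = accrue_qalys(
        trace,
        utilities,
        rate,
        half_cycle=half,
        pf_no_sse_late=config[f"utilities.pf_no_sse.{ARM_BSC}"],
        window_weeks=None if window is None else float(window),
    )
    ly_undisc = accrue_life_years(trace, 0.0, half_cycle=half)
    ly_disc = accrue_life_years(trace, rate, half_cycle=half)

    drug, admin = drug_and_admin_cost(config, arm)
    mgmt = management_cost(trace, config, rate, half_cycle=half)
    hosp, daycare, visits = facility_costs(trace, config, rate, arm, half_cycle=half)
    ae = ae_cost(trace, config, rate, arm, half_cycle=half)
    sse = sse_event_cost(trace.new_first_sse, trace, config, rate, arm)
    eol, second = terminal_and_secondline_costs(trace, config, rate, arm)

    breakdown = CostBreakdown(
        drug=drug,
        administration=admin,
        patient_management=mgmt,
        hospitalization=hosp,
        day_care=daycare,
        physician_visits=visits,
        second_line=second,
        end_of_life=eol,
        sse=sse,
        adverse_events=ae,
    )
    reported_ly = ly_disc if config.values.get("discount_life_years", False) else ly_undisc
    return ArmResult(
        arm=arm,
        life_years=reported_ly,
        life_years_discounted=ly_disc,
        qalys=qalys,
        costs=breakdown,
    )


def compute_icer(reference: ArmResult, comparator: ArmResult) -> CEAResult:
    """Incremental statistics of ``reference`` (radium-223) vs ``comparator``."""
    return CEAResult(reference=reference, comparator=comparator)


def net_monetary_benefit(result: CEAResult, wtp: float) -> float:
    """``wtp * dQALY - dCost`` at willingness-to-pay ``wtp`` (EUR/QALY)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * result.delta_qalys - result.delta_cost
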