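"""Discounted life years, QALYs, costs, and incremental cost-effectiveness.

Conventions (fixed, see docs/methods.md):

* outcomes and costs accrued in cycle t are discounted by
  ``(1 + r)**(-t/12)`` with r the annual rate (3% by default);
* the index procedure is billed once at time zero (undiscounted);
* event costs are billed in full in the cycle of occurrence;
* re-interventions are billed at the respective procedure cost;
* rehabilitation (micro-costing scenario only) is billed once at cycle 1 to
  the uptake fraction of the cohort.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markov_engine import CohortTrace, run_arm_trace
from .parameters import EVENT_COST_ITEM, ParameterSet, UtilityTable, ValidationError


def discount_factor(cycle: int | np.ndarray, annual_rate: float) -> float | np.ndarray:
    """Discount factor ``(1 + r)**(-cycle/12)`` for a monthly cycle index."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    cycle = np.asarray(cycle)
    if (cycle < 0).any():
        raise ValueError("cycle must be >= 0")
    out = (1.0 + annual_rate) ** (-cycle / 12.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class ArmResult:
    """Discounted and undiscounted totals for one strategy arm."""

    arm: str
    discounted_cost: float
    undiscounted_cost: float
    discounted_qaly: float
    undiscounted_qaly: float
    discounted_ly: float
    undiscounted_ly: float
    cost_breakdown: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "arm": self.arm,
            "discounted_cost": self.discounted_cost,
            "undiscounted_cost": self.undiscounted_cost,
            "discounted_qaly": self.discounted_qaly,
            "undiscounted_qaly": self.undiscounted_qaly,
            "discounted_ly": self.discounted_ly,
            "undiscounted_ly": self.undiscounted_ly,
            "cost_breakdown": dict(self.cost_breakdown),
        }


@dataclass
class CEResult:
    """Incremental quantities of intervention vs comparator."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icur: float | None  # euros per QALY gained
    icer: float | None  # euros per life year gained
    dominance: str = "none"  # none | intervention_dominant | intervention_dominated

    def as_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_ly": self.delta_ly,
            "icur": self.icur,
            "icer": self.icer,
            "dominance": self.dominance,
        }


def _weights(trace: CohortTrace, half_cycle: bool) -> np.ndarray:
    """Occupancy weights per cycle 1..H; the half-cycle correction averages
    the start and end of each cycle instead of using the end."""
    occ = trace.occupancy
    return 0.5 * (occ[:-1] + occ[1:]) if half_cycle else occ[1:]


def accrue_life_years(
    trace: CohortTrace, annual_rate: float, half_cycle: bool = False
) -> tuple[float, float]:
    """(discounted, undiscounted) life years: alive time in 1/12-year cycles."""
    w = _weights(trace, half_cycle)
    alive = 1.0 - w[:, -1]
    d = discount_factor(np.arange(1, len(alive) + 1), annual_rate)
    return float(np.sum(alive * d) / 12.0), float(np.sum(alive) / 12.0)


def accrue_qalys(
    trace: CohortTrace,
    utilities: UtilityTable,
    annual_rate: float,
    half_cycle: bool = False,
) -> tuple[float, float]:
    """(discounted, undiscounted) QALYs: utility-weighted state occupancy."""
    u = utilities.vector(trace.arm)
    w = _weights(trace, half_cycle)
    per_cycle = w @ u
    d = discount_factor(np.arange(1, len(per_cycle) + 1), annual_rate)
    return float(np.sum(per_cycle * d) / 12.0), float(np.sum(per_cycle) / 12.0)


def accrue_costs(
    trace: CohortTrace,
    params: ParameterSet,
    arm: str,
    annual_rate: float | None = None,
    scenario_mode: bool = False,
) -> tuple[float, float, dict[str, float]]:
    """(discounted, undiscounted, per-item discounted breakdown).

    The breakdown keys are ``index_procedure``, each billed event category,
    and ``rehabilitation`` in scenario mode; components sum to the total.
    """
    if annual_rate is None:
        annual_rate = params.settings.annual_discount_rate
    h = trace.horizon_cycles
    d = discount_factor(np.arange(1, h + 1), annual_rate)

    breakdown: dict[str, float] = {}
    index = params.index_cost(arm, scenario_mode=scenario_mode)
    breakdown["index_procedure"] = index
    disc = index
    undisc = index

    for event, counts in trace.incidence.items():
        item = EVENT_COST_ITEM.get(event)
        if item is None:
            continue
        try:
            unit = params.costs.cost_of(item)
        except KeyError as exc:
            raise ValidationError(
                f"no unit cost for incident event {event!r} (item {item!r})"
            ) from exc
        # re-interventions are billed at the tariff procedure cost in every
        # mode: the micro-costing scenario re-prices the index procedure only
        breakdown[event] = float(np.sum(counts * unit * d))
        disc += breakdown[event]
        undisc += float(np.sum(counts * unit))

    if scenario_mode:
        uptake = params.rehabilitation.uptake.get(arm, 0.0)
        if uptake > 0.0 and params.rehabilitation.unit_cost is None:
            raise ValidationError(
                f"scenario mode requires a rehabilitation unit cost "
                f"(uptake for {arm!r} is {uptake})"
            )
        rehab_unit = params.rehabilitation.unit_cost or 0.0
        rehab = uptake * rehab_unit
        breakdown["rehabilitation"] = rehab * (d[0] if h >= 1 else 1.0)
        disc += breakdown["rehabilitation"]
        undisc += rehab
    return disc, undisc, breakdown


def run_arm(params: ParameterSet, arm: str, scenario_mode: bool = False) -> ArmResult:
    """Trace one arm and accrue all discounted/undiscounted totals."""
    trace = run_arm_trace(params, arm)
    rate = params.settings.annual_discount_rate
    hcc = params.settings.half_cycle_correction
    ly_d, ly_u = accrue_life_years(trace, rate, hcc)
    qaly_d, qaly_u = accrue_qalys(trace, params.utilities, rate, hcc)
    cost_d, cost_u, breakdown = accrue_costs(
        trace, params, arm, rate, scenario_mode=scenario_mode
    )
    return ArmResult(
        arm=arm,
        discounted_cost=cost_d,
        undiscounted_cost=cost_u,
        discounted_qaly=qaly_d,
        undiscounted_qaly=qaly_u,
        discounted_ly=ly_d,
        undiscounted_ly=ly_u,
        cost_breakdown=breakdown,
    )


def compute_ce(intervention: ArmResult, comparator: ArmResult) -> CEResult:
    """Incremental cost-effectiveness on unrounded deltas.

    Ratios are formed only when the effect delta is positive; with opposite
    beneficial signs the dominance flag carries the verdict and the ratio is
    left undefined (``None``), never raised as an error.
    """
    dc = intervention.discounted_cost - comparator.discounted_cost
    dq = intervention.discounted_qaly - comparator.discounted_qaly
    dl = intervention.discounted_ly - comparator.discounted_ly

    dominance = "none"
    if dc < 0 and dq > 0:
        dominance = "intervention_dominant"
    elif dc > 0 and dq < 0:
        dominance = "intervention_dominated"

    icur = dc / dq if dq > 0 and dominance == "none" else None
    icer = dc / dl if dl > 0 and dominance == "none" else None
    return CEResult(
        delta_cost=dc, delta_qaly=dq, delta_ly=dl,
        icur=icur, icer=icer, dominance=dominance,
    )


def run_comparison(
    params: ParameterSet, scenario_mode: bool = False
) -> tuple[ArmResult, ArmResult, CEResult]:
    """Run both configured arms and their incremental comparison."""
    intervention, comparator = params.settings.arms
    a = run_arm(params, intervention, scenario_mode=scenario_mode)
    b = run_arm(params, comparator, scenario_mode=scenario_mode)
    return a, b, compute_ce(a, b)
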