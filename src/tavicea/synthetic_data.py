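"""Synthetic stand-ins for the unavailable supplementary inputs.

The published model relies on two supplementary tables that are not
available here: monthly NYHA-class transition matrices per arm and
health-state utilities.  This module generates statistically structured
substitutes — interventional arms improve functional class (most strongly in
the first year), the medical-therapy arm progresses, utilities decrease with
NYHA class and carry a stroke decrement — plus fully synthetic parameter
sets with closed-form expected outputs used to verify the whole pipeline.

These values are NOT the published ones.  Any quantity that depends on them
(QALYs, hence ICURs) is a demonstration, not a reproduction; supply real
tables through the standard CSV schemas to override them.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .parameters import (
    CostTable,
    IntervalProbabilityTable,
    ModelSettings,
    ParameterSet,
    Rehabilitation,
    TimeInterval,
    UtilityTable,
    EVENT_CATEGORIES,
)


def _default_improvement() -> dict[str, float]:
    # monthly propensity to move one NYHA class toward I after an effective
    # valve procedure; medical therapy confers none
    return {"tavi": 0.30, "savr": 0.25, "medical": 0.0}


def _default_progression() -> dict[str, float]:
    # monthly propensity to deteriorate one class; dominant under medical therapy
    return {"tavi": 0.01, "savr": 0.01, "medical": 0.06}


@dataclass
class SyntheticConfig:
    """Knobs for the synthetic NYHA dynamics and utilities."""

    seed: int = 0
    improvement_strength: dict[str, float] = field(default_factory=_default_improvement)
    progression_strength: dict[str, float] = field(default_factory=_default_progression)
    #: improvement applies at full strength for this many cycles, then decays
    early_cycles: int = 12
    late_factor: float = 0.25
    #: annual utility per NYHA class I..IV, strictly decreasing
    utility_gradient: tuple[float, ...] = (0.85, 0.75, 0.65, 0.55)
    stroke_utility_decrement: float = 0.10
    utility_arm_offset: dict[str, float] = field(default_factory=dict)
    event_rate_scale: float = 1.0

    def __post_init__(self) -> None:
        self.improvement_strength = {**_default_improvement(), **self.improvement_strength}
        self.progression_strength = {**_default_progression(), **self.progression_strength}
        if isinstance(self.utility_gradient, list):
            self.utility_gradient = tuple(self.utility_gradient)


def _shift_matrix(improve: float, progress: float) -> np.ndarray:
    """Single-cycle 4x4 matrix: ``improve`` moves one class toward NYHA I,
    ``progress`` one class toward NYHA IV, remainder stays."""
    if improve + progress > 1.0:
        total = improve + progress
        improve, progress = improve / total, progress / total
    m = np.zeros((4, 4))
    for k in range(4):
        up = improve if k > 0 else 0.0
        down = progress if k < 3 else 0.0
        m[k, k] = 1.0 - up - down
        if k > 0:
            m[k, k - 1] = up
        if k < 3:
            m[k, k + 1] = down
    return m


def generate_nyha_transitions(
    config: SyntheticConfig, arm: str, horizon_cycles: int = 180
) -> np.ndarray:
    """``(horizon, 4, 4)`` row-stochastic monthly matrices for one arm.

    Improvement is strongest during ``config.early_cycles`` (post-procedure
    recovery) and decays to ``late_factor`` of its strength afterwards.
    Deterministic for a given config.
    """
    s = config.improvement_strength.get(arm, 0.0)
    p = config.progression_strength.get(arm, 0.0)
    early = _shift_matrix(s, p)
    late = _shift_matrix(s * config.late_factor, p)
    out = np.empty((horizon_cycles, 4, 4))
    cut = min(config.early_cycles, horizon_cycles)
    out[:cut] = early
    out[cut:] = late
    return out


def generate_utilities(config: SyntheticConfig) -> UtilityTable:
    """Per-state annual utilities: decreasing in NYHA class, stroke history
    subtracts a fixed decrement (floored at 0), death is 0 by construction."""
    g = config.utility_gradient
    if len(g) != 4 or any(b >= a for a, b in zip(g, g[1:])):
        raise ValueError("utility gradient must be 4 strictly decreasing values")
    if not 0.0 <= config.stroke_utility_decrement <= 1.0:
        raise ValueError("stroke utility decrement must lie in [0, 1]")
    values: dict[tuple[int, bool, str], float] = {}
    for arm in ("tavi", "savr", "medical"):
        off = config.utility_arm_offset.get(arm, 0.0)
        for nyha in range(1, 5):
            base = min(1.0, max(0.0, g[nyha - 1] + off))
            values[(nyha, False, arm)] = base
            values[(nyha, True, arm)] = max(0.0, base - config.stroke_utility_decrement)
    return UtilityTable(values=values)


# ---------------------------------------------------------------------------
# Ground-truth parameter sets with closed-form expectations
# ---------------------------------------------------------------------------

def _constant_hazard_table(event: str, arm: str, monthly_p: float) -> IntervalProbabilityTable:
    """Interval table whose banded probabilities convert back to a constant
    monthly hazard, mimicking the real table layout."""
    bands = (
        [(1, 1), (2, 6), (7, 12), (13, 24), (25, 36), (37, 48), (49, 60)]
        if event == "mortality"
        else [(1, 1), (2, 6), (7, 12), (13, 24)]
    )
    entries = tuple(
        (TimeInterval(s, e), 1.0 - (1.0 - monthly_p) ** (e - s + 1)) for s, e in bands
    )
    return IntervalProbabilityTable(event=event, arm=arm, entries=entries)


def generate_ground_truth_set(
    monthly_mortality: float = 0.02,
    utility: float = 1.0,
    annual_discount_rate: float = 0.0,
    horizon_cycles: int = 120,
    event_rate: float = 0.0,
    event_cost: float = 0.0,
    index_cost: float = 10000.0,
    risk_group: str = "inoperable",
) -> tuple[ParameterSet, dict[str, float]]:
    """Degenerate regime (constant hazards, frozen NYHA class, flat utilities)
    whose discounted LY, QALY and cost have geometric-series closed forms.

    Returns the parameter set and, per arm, the analytic expectations the full
    pipeline must reproduce to numerical precision.  Both arms are identical;
    the single billed event category is ``hosp_as``.
    """
    settings = ModelSettings(
        risk_group=risk_group,
        horizon_cycles=horizon_cycles,
        annual_discount_rate=annual_discount_rate,
        initial_nyha_distribution=(0.0, 1.0, 0.0, 0.0),
    )
    events: dict[str, dict[str, IntervalProbabilityTable]] = {}
    nyha: dict[str, np.ndarray] = {}
    for arm in settings.arms:
        tables = {}
        for event in EVENT_CATEGORIES:
            if event == "mortality":
                p = monthly_mortality
            elif event == "hosp_as":
                p = event_rate
            else:
                p = 0.0
            tables[event] = _constant_hazard_table(event, arm, p)
        events[arm] = tables
        nyha[arm] = np.broadcast_to(np.eye(4), (max(horizon_cycles, 1), 4, 4)).copy()

    utilities = UtilityTable(
        values={
            (k, s, arm): utility
            for k in range(1, 5)
            for s in (False, True)
            for arm in ("tavi", "savr", "medical")
        }
    )
    unit_costs = {item: 0.0 for item in (
        "major_stroke", "tia", "atrial_fibrillation", "renal_replacement",
        "myocardial_infarction", "new_pacemaker", "major_bleeding",
        "major_vascular", "hosp_hf", "balloon_valvuloplasty", "endocarditis",
    )}
    unit_costs["hosp_as"] = event_cost
    costs = CostTable(
        unit_costs=unit_costs,
        index_costs={arm: index_cost for arm in ("tavi", "savr", "medical")},
    )
    params = ParameterSet(
        settings=settings,
        events=events,
        nyha_transitions=nyha,
        utilities=utilities,
        costs=costs,
        rehabilitation=Rehabilitation(),
    ).validate()

    # closed forms: alive(t) = (1-q)^t; discount d(t) = (1+r)^(-t/12);
    # survivors at risk in cycle t equal alive(t), so every accrual is a
    # geometric series in x = (1-q) * (1+r)^(-1/12)
    q, r, h = monthly_mortality, annual_discount_rate, horizon_cycles
    x = (1.0 - q) * (1.0 + r) ** (-1.0 / 12.0)
    geom = h * 1.0 if x == 1.0 else x * (1.0 - x**h) / (1.0 - x)
    ly = geom / 12.0
    expectations = {
        "discounted_ly": ly,
        "discounted_qaly": utility * ly,
        "discounted_cost": index_cost + event_cost * event_rate * geom,
    }
    return params, expectations


# ---------------------------------------------------------------------------
# CSV export (same schemas the loader reads)
# ---------------------------------------------------------------------------

def write_parameter_csvs(params: ParameterSet, outdir: str | Path) -> dict[str, Path]:
    """Serialize a parameter set to the loader's CSV schemas, so synthetic
    and fixture inputs are interchangeable.  Probabilities are written as
    decimal fractions (load with ``percent: false``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["events"] = outdir / "events.csv"
    with open(paths["events"], "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["risk_group", "arm", "event", "start_month", "end_month", "probability"])
        for arm, tables in sorted(params.events.items()):
            for event in EVENT_CATEGORIES:
                for iv, p in tables[event].entries:
                    w.writerow([
                        params.settings.risk_group, arm, event,
                        iv.start_month, iv.end_month, repr(float(p)),
                    ])

    paths["costs"] = outdir / "costs.csv"
    with open(paths["costs"], "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["item", "euros"])
        for arm, c in sorted(params.costs.index_costs.items()):
            if arm == "medical" and c == 0.0:
                continue
            w.writerow([f"{arm}_procedure", repr(float(c))])
        for item, c in sorted(params.costs.unit_costs.items()):
            w.writerow([item, repr(float(c))])

    paths["utilities"] = outdir / "utilities.csv"
    with open(paths["utilities"], "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["state", "arm", "utility"])
        for (nyha, stroke, arm), u in sorted(
            params.utilities.values.items(), key=lambda kv: (kv[0][2], kv[0][0], kv[0][1])
        ):
            state = f"nyha{nyha}" + ("_stroke" if stroke else "")
            w.writerow([state, arm, repr(float(u))])

    paths["nyha_transitions"] = outdir / "nyha_transitions.csv"
    with open(paths["nyha_transitions"], "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["arm", "start_cycle", "end_cycle", "from_nyha", "to_nyha", "probability"])
        for arm, m in sorted(params.nyha_transitions.items()):
            m = np.asarray(m)
            if m.ndim == 2:
                m = m[None, ...]
            # compress consecutive identical cycles into bands
            start = 0
            for t in range(1, m.shape[0] + 1):
                if t == m.shape[0] or not np.array_equal(m[t], m[start]):
                    for i in range(4):
                        for j in range(4):
                            if m[start, i, j] != 0.0:
                                w.writerow([arm, start + 1, t, i + 1, j + 1, repr(float(m[start, i, j]))])
                    start = t
    return paths
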