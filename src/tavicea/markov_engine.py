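"""Cohort state-transition engine.

State space (9 states): NYHA classes I-IV without stroke history
(indices 0-3), NYHA I-IV with stroke history (4-7), and death (8, the single
absorbing state).  Within each monthly cycle three competing steps compose in
a fixed, documented order:

1. death, with the cycle's arm-level mortality probability, from every living
   state (mortality is arm-level, so it must act first and uniformly);
2. among survivors, major stroke moves the struck fraction from a no-stroke
   state to the same-NYHA stroke-history state (class is kept, the flag flips);
3. among survivors, NYHA redistribution by the arm's monthly 4x4 matrix,
   applied identically inside the no-stroke and stroke blocks so the stroke
   flag is never cleared.

All other clinical events (bleeding, pacemaker, hospitalizations, ...) do not
define states: they are recorded as expected incidences per cycle —
(survivor fraction at risk) x (per-cycle probability) — and billed downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    EVENT_CATEGORIES,
    ParameterSet,
    extend_event_rates,
    extrapolate_mortality,
)

N_STATES = 9
DEATH = 8

STATE_LABELS: tuple[str, ...] = tuple(
    f"nyha{k}" + ("_stroke" if s else "") for s in (False, True) for k in range(1, 5)
) + ("death",)


def state_index(nyha_class: int, stroke_history: bool, alive: bool = True) -> int:
    """Index of a health state; death ignores class and history."""
    if not alive:
        return DEATH
    if not 1 <= nyha_class <= 4:
        raise ValueError(f"NYHA class must be 1-4, got {nyha_class}")
    return (4 if stroke_history else 0) + nyha_class - 1


@dataclass
class TransitionModel:
    """Per-cycle 9x9 row-stochastic matrices plus the event-rate sequences
    needed to record incidences while iterating."""

    arm: str
    matrices: np.ndarray  # (horizon, 9, 9)
    mortality: np.ndarray  # (horizon,)
    event_rates: dict[str, np.ndarray] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def horizon_cycles(self) -> int:
        return self.matrices.shape[0]

    def validate(self, atol: float = 1e-10) -> None:
        if self.horizon_cycles == 0:
            return
        if np.abs(self.matrices.sum(axis=2) - 1.0).max() > atol:
            raise ValueError("transition rows do not sum to 1")
        if self.matrices.min() < -atol:
            raise ValueError("negative transition probability")
        death_rows = self.matrices[:, DEATH, :]
        expected = np.zeros(N_STATES)
        expected[DEATH] = 1.0
        if np.abs(death_rows - expected).max() > atol:
            raise ValueError("death is not absorbing")
        # stroke history is never cleared
        if np.abs(self.matrices[:, 4:8, 0:4]).max() > atol:
            raise ValueError("transition from stroke-history to no-stroke state")


@dataclass
class CohortTrace:
    """State occupancancy per cycle (row 0 = start distribution) and expected
    per-member event incidences per cycle."""

    arm: str
    occupancy: np.ndarray  # (horizon+1, 9)
    incidence: dict[str, np.ndarray]  # event -> (horizon,)

    @property
    def horizon_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self) -> np.ndarray:
        """Living fraction at the end of each cycle 0..horizon."""
        return 1.0 - self.occupancy[:, DEATH]

    def validate(self, atol: float = 1e-9) -> None:
        if np.abs(self.occupancy.sum(axis=1) - 1.0).max() > atol:
            raise ValueError("occupancy rows do not sum to 1")
        death = self.occupancy[:, DEATH]
        if death.size > 1 and np.diff(death).min() < -atol:
            raise ValueError("death occupancy decreased")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATE_LABELS))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        for event, inc in self.incidence.items():
            df[f"events_{event}"] = np.concatenate([[0.0], inc])
        return df


def build_transition_matrices(params: ParameterSet, arm: str) -> TransitionModel:
    """Compose death, major stroke and NYHA movement into per-cycle matrices."""
    if arm not in params.nyha_transitions:
        raise ValueError(f"no NYHA transition matrix for arm {arm!r}")
    settings = params.settings
    h = settings.horizon_cycles
    tables = params.events[arm]

    q, warnings = extrapolate_mortality(
        tables["mortality"], h,
        mode=settings.extrapolation_mode,
        fit_years=settings.mortality_fit_years,
    ) if h > 0 else (np.zeros(0), [])
    event_rates = {
        ev: extend_event_rates(tables[ev], h)
        for ev in EVENT_CATEGORIES
        if ev != "mortality"
    } if h > 0 else {}

    nyha = np.asarray(params.nyha_transitions[arm], dtype=float)
    if nyha.ndim == 2:
        nyha = np.broadcast_to(nyha, (h, 4, 4))
    elif nyha.shape[0] < h:
        raise ValueError(
            f"NYHA matrix stack for {arm!r} covers {nyha.shape[0]} cycles, "
            f"horizon is {h}"
        )
    else:
        nyha = nyha[:h]

    s = event_rates.get("major_stroke", np.zeros(h))
    surv = 1.0 - q
    mats = np.zeros((h, N_STATES, N_STATES))
    # no-stroke block: survive, maybe stroke (flip flag), then NYHA movement
    mats[:, 0:4, 0:4] = (surv * (1.0 - s))[:, None, None] * nyha
    mats[:, 0:4, 4:8] = (surv * s)[:, None, None] * nyha
    # stroke-history block: survive, NYHA movement within the block
    mats[:, 4:8, 4:8] = surv[:, None, None] * nyha
    mats[:, 0:8, DEATH] = q[:, None]
    mats[:, DEATH, DEATH] = 1.0

    model = TransitionModel(
        arm=arm, matrices=mats, mortality=q, event_rates=event_rates,
        warnings=list(warnings),
    )
    model.validate()
    return model


def run_cohort(
    model: TransitionModel,
    initial_distribution: np.ndarray | None = None,
    horizon_cycles: int | None = None,
) -> CohortTrace:
    """Iterate ``occupancy(t) = occupancy(t-1) @ matrix(t)`` and record the
    expected event count per cohort member each cycle.

    The at-risk pool for events in cycle t is the fraction still alive after
    that cycle's deaths (consistent with the death-first composition order).
    """
    h = model.horizon_cycles if horizon_cycles is None else horizon_cycles
    if h > model.horizon_cycles:
        raise ValueError(
            f"horizon {h} exceeds the {model.horizon_cycles} available matrices"
        )
    if initial_distribution is None:
        initial_distribution = np.zeros(N_STATES)
        initial_distribution[1:4] = 1.0 / 3.0
    init = np.asarray(initial_distribution, dtype=float)
    if init.shape != (N_STATES,) or abs(init.sum() - 1.0) > 1e-9 or init.min() < 0:
        raise ValueError("initial distribution must be 9 non-negative fractions summing to 1")

    occupancy = np.empty((h + 1, N_STATES))
    occupancy[0] = init
    for t in range(1, h + 1):
        occupancy[t] = occupancy[t - 1] @ model.matrices[t - 1]

    alive = 1.0 - occupancy[:, DEATH]
    at_risk = alive[:-1] * (1.0 - model.mortality[:h])  # survivors of cycle t
    incidence = {
        event: at_risk * rates[:h] for event, rates in model.event_rates.items()
    }
    trace = CohortTrace(arm=model.arm, occupancy=occupancy, incidence=incidence)
    trace.validate()
    return trace


def run_arm_trace(params: ParameterSet, arm: str) -> CohortTrace:
    """Convenience: build the transition model and run the cohort from the
    configured initial NYHA distribution (all alive, no stroke history)."""
    model = build_transition_matrices(params, arm)
    init = np.zeros(N_STATES)
    init[0:4] = np.asarray(params.settings.initial_nyha_distribution, dtype=float)
    return run_cohort(model, init)
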