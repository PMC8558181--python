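"""Model inputs: loading, validation, and probability transforms.

All clinical inputs are expressed as *interval probabilities*: the chance of
an event (or death) occurring within a 1-based, inclusive band of months,
conditional on being alive and at risk at the band start.  The model runs on
1-month cycles, so every table is converted to a per-cycle probability
sequence with the constant-rate compounding formula
``p_cycle = 1 - (1 - p_interval)**(1/n)``, which reproduces the interval
total exactly when compounded back.

Mortality tables cover at least 60 months and are extended to the model
horizon by a linear (ordinary-least-squares) trend fitted to the annualized
probabilities of years 2-5; other event tables cover at least 24 months and
carry their last observed band forward unchanged.
"""
from __future__ import annotations

import copy
import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger("tavicea")

# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

#: Event categories modelled as costed incidences (plus mortality and major
#: stroke, which also shape the state space).
EVENT_CATEGORIES: tuple[str, ...] = (
    "mortality",
    "major_stroke",
    "tia",
    "atrial_fibrillation",
    "renal_replacement",
    "myocardial_infarction",
    "new_pacemaker",
    "major_bleeding",
    "major_vascular",
    "hosp_as",
    "hosp_hf",
    "balloon_valvuloplasty",
    "re_tavi",
    "re_savr",
    "endocarditis",
)

ARMS: tuple[str, ...] = ("tavi", "savr", "medical")
RISK_GROUPS: tuple[str, ...] = ("intermediate", "high", "inoperable")

#: Comparator strategy per surgical-risk group: surgical replacement for
#: operable patients, medical therapy for inoperable ones.
COMPARATOR_FOR_GROUP: dict[str, str] = {
    "intermediate": "savr",
    "high": "savr",
    "inoperable": "medical",
}

#: Unit-cost item billed per event category (``None`` = not billed).
#: Re-interventions are billed at the respective index procedure cost.
EVENT_COST_ITEM: dict[str, str | None] = {
    "mortality": None,
    "major_stroke": "major_stroke",
    "tia": "tia",
    "atrial_fibrillation": "atrial_fibrillation",
    "renal_replacement": "renal_replacement",
    "myocardial_infarction": "myocardial_infarction",
    "new_pacemaker": "new_pacemaker",
    "major_bleeding": "major_bleeding",
    "major_vascular": "major_vascular",
    "hosp_as": "hosp_as",
    "hosp_hf": "hosp_hf",
    "balloon_valvuloplasty": "balloon_valvuloplasty",
    "re_tavi": "index:tavi",
    "re_savr": "index:savr",
    "endocarditis": "endocarditis",
}

DATA_DIR = Path(__file__).parent / "data"


class ValidationError(ValueError):
    """Raised when an input table violates a model invariant.

    The message names the offending cell (event, arm, band, value).
    """


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeInterval:
    """Closed, 1-based band of months since the index procedure."""

    start_month: int
    end_month: int

    def __post_init__(self) -> None:
        if self.start_month < 1 or self.end_month < self.start_month:
            raise ValidationError(
                f"invalid interval [{self.start_month}, {self.end_month}]"
            )

    @property
    def n_cycles(self) -> int:
        return self.end_month - self.start_month + 1


@dataclass(frozen=True)
class IntervalProbabilityTable:
    """Interval probabilities of one event category for one arm."""

    event: str
    arm: str
    entries: tuple[tuple[TimeInterval, float], ...]

    def validate(self) -> None:
        if not self.entries:
            raise ValidationError(f"{self.event}/{self.arm}: empty table")
        if self.event not in EVENT_CATEGORIES:
            raise ValidationError(f"unknown event category {self.event!r}")
        expected_start = 1
        for iv, p in self.entries:
            if iv.start_month != expected_start:
                raise ValidationError(
                    f"{self.event}/{self.arm}: band starting at month "
                    f"{iv.start_month} is not contiguous (expected "
                    f"{expected_start})"
                )
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"{self.event}/{self.arm}: probability {p} for months "
                    f"{iv.start_month}-{iv.end_month} outside [0, 1]"
                )
            expected_start = iv.end_month + 1
        min_cover = 60 if self.event == "mortality" else 24
        if self.last_month < min_cover:
            raise ValidationError(
                f"{self.event}/{self.arm}: table covers {self.last_month} "
                f"months, needs >= {min_cover}"
            )

    @property
    def last_month(self) -> int:
        return self.entries[-1][0].end_month

    def scaled(self, factor: float) -> "IntervalProbabilityTable":
        """Multiply every interval probability, clamping to [0, 1]."""
        return replace(
            self,
            entries=tuple(
                (iv, min(1.0, max(0.0, p * factor))) for iv, p in self.entries
            ),
        )

    def with_probabilities(self, probs: Sequence[float]) -> "IntervalProbabilityTable":
        if len(probs) != len(self.entries):
            raise ValueError("probability count mismatch")
        return replace(
            self, entries=tuple((iv, float(p)) for (iv, _), p in zip(self.entries, probs))
        )


@dataclass
class CostTable:
    """Unit costs (euros) per billed item and per-arm index procedure costs."""

    unit_costs: dict[str, float]
    index_costs: dict[str, float]

    def validate(self) -> None:
        for item, c in {**self.unit_costs, **self.index_costs}.items():
            if c < 0 or not math.isfinite(c):
                raise ValidationError(f"cost for {item!r} is {c}, must be >= 0")

    def cost_of(self, item: str) -> float:
        if item.startswith("index:"):
            return self.index_costs[item.split(":", 1)[1]]
        return self.unit_costs[item]


@dataclass
class UtilityTable:
    """Annual health-state utilities per (NYHA class, stroke history, arm).

    Death has utility 0 by construction and is not stored.
    """

    values: dict[tuple[int, bool, str], float]

    def validate(self, arms: Iterable[str]) -> None:
        for arm in arms:
            for nyha in range(1, 5):
                for stroke in (False, True):
                    key = (nyha, stroke, arm)
                    if key not in self.values:
                        raise ValidationError(
                            f"missing utility for NYHA {nyha}, "
                            f"stroke={stroke}, arm={arm}"
                        )
                    u = self.values[key]
                    if not 0.0 <= u <= 1.0:
                        raise ValidationError(
                            f"utility {u} for NYHA {nyha}, stroke={stroke}, "
                            f"arm={arm} outside [0, 1]"
                        )
                if self.values[(nyha, True, arm)] > self.values[(nyha, False, arm)]:
                    raise ValidationError(
                        f"stroke-history utility exceeds no-stroke utility "
                        f"for NYHA {nyha}, arm={arm}"
                    )

    def vector(self, arm: str) -> np.ndarray:
        """Utilities ordered as the engine's 9-state space (death last, 0)."""
        u = np.zeros(9)
        for nyha in range(1, 5):
            u[nyha - 1] = self.values[(nyha, False, arm)]
            u[nyha + 3] = self.values[(nyha, True, arm)]
        return u


@dataclass
class Rehabilitation:
    """Post-procedure rehabilitation, billed only in the micro-costing scenario."""

    uptake: dict[str, float] = field(default_factory=dict)
    unit_cost: float | None = None

    def validate(self) -> None:
        for arm, f in self.uptake.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"rehabilitation uptake {f} for {arm} outside [0, 1]")
        if self.unit_cost is not None and self.unit_cost < 0:
            raise ValidationError(f"rehabilitation unit cost {self.unit_cost} < 0")


@dataclass
class ModelSettings:
    """Run-level settings; the cycle length is fixed at one month."""

    risk_group: str
    comparator: str | None = None
    intervention: str = "tavi"
    horizon_cycles: int = 180
    annual_discount_rate: float = 0.03
    cycle_length_months: int = 1
    #: Cohort start: fractions over NYHA I-IV, everyone alive without stroke
    #: history.  Default is uniform over classes II-IV.
    initial_nyha_distribution: tuple[float, ...] = (0.0, 1 / 3, 1 / 3, 1 / 3)
    half_cycle_correction: bool = False
    #: "interval": OLS on annualized interval probabilities (default);
    #: "cumulative": OLS on the cumulative death fraction.
    extrapolation_mode: str = "interval"
    mortality_fit_years: tuple[int, int] = (2, 5)

    def __post_init__(self) -> None:
        if self.comparator is None:
            self.comparator = COMPARATOR_FOR_GROUP.get(self.risk_group)

    def validate(self) -> None:
        if self.risk_group not in RISK_GROUPS:
            raise ValidationError(f"unknown risk group {self.risk_group!r}")
        if self.comparator != COMPARATOR_FOR_GROUP[self.risk_group]:
            raise ValidationError(
                f"comparator {self.comparator!r} invalid for risk group "
                f"{self.risk_group!r} (expected "
                f"{COMPARATOR_FOR_GROUP[self.risk_group]!r})"
            )
        if self.cycle_length_months != 1:
            raise ValidationError("cycle length is fixed at 1 month")
        if self.horizon_cycles < 0:
            raise ValidationError("horizon_cycles must be >= 0")
        if self.annual_discount_rate < 0:
            raise ValidationError("discount rate must be >= 0")
        if self.extrapolation_mode not in ("interval", "cumulative"):
            raise ValidationError(
                f"unknown extrapolation mode {self.extrapolation_mode!r}"
            )
        dist = np.asarray(self.initial_nyha_distribution, dtype=float)
        if dist.shape != (4,) or dist.min() < 0 or abs(dist.sum() - 1.0) > 1e-9:
            raise ValidationError("initial NYHA distribution must be 4 non-negative fractions summing to 1")

    @property
    def arms(self) -> tuple[str, str]:
        return (self.intervention, self.comparator)


@dataclass
class ParameterSet:
    """Complete, validated inputs for one risk group.

    ``events[arm][event]`` holds the interval tables; ``nyha_transitions[arm]``
    a ``(horizon, 4, 4)`` (or ``(4, 4)``) row-stochastic monthly matrix stack.
    """

    settings: ModelSettings
    events: dict[str, dict[str, IntervalProbabilityTable]]
    nyha_transitions: dict[str, np.ndarray]
    utilities: UtilityTable
    costs: CostTable
    rehabilitation: Rehabilitation = field(default_factory=Rehabilitation)
    scenario_index_costs: dict[str, float] | None = None
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> "ParameterSet":
        self.settings.validate()
        for arm in self.settings.arms:
            if arm not in self.events:
                raise ValidationError(f"no event tables for arm {arm!r}")
            for event in EVENT_CATEGORIES:
                if event not in self.events[arm]:
                    raise ValidationError(f"missing event column {event!r} for arm {arm!r}")
                self.events[arm][event].validate()
            if arm not in self.nyha_transitions:
                raise ValidationError(f"missing NYHA transition matrix for arm {arm!r}")
            m = np.asarray(self.nyha_transitions[arm], dtype=float)
            if m.shape[-2:] != (4, 4):
                raise ValidationError(f"NYHA matrix for {arm!r} is not 4x4")
            if m.min() < -1e-12 or np.abs(m.sum(axis=-1) - 1.0).max() > 1e-9:
                raise ValidationError(f"NYHA matrix for {arm!r} is not row-stochastic")
        self.utilities.validate(self.settings.arms)
        self.costs.validate()
        self.rehabilitation.validate()
        for arm in self.settings.arms:
            if arm not in self.costs.index_costs:
                raise ValidationError(f"missing index procedure cost for arm {arm!r}")
        if self.scenario_index_costs is not None:
            for arm, c in self.scenario_index_costs.items():
                if c < 0:
                    raise ValidationError(f"scenario index cost for {arm!r} is {c} < 0")
        return self

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def index_cost(self, arm: str, scenario_mode: bool = False) -> float:
        if scenario_mode and self.scenario_index_costs and arm in self.scenario_index_costs:
            return self.scenario_index_costs[arm]
        return self.costs.index_costs.get(arm, 0.0)


# ---------------------------------------------------------------------------
# Probability transforms
# ---------------------------------------------------------------------------

def interval_to_cycle_probability(p_interval: float, n_cycles: int) -> float:
    """Constant per-cycle probability reproducing ``p_interval`` over ``n_cycles``.

    ``1 - (1 - p)**(1/n)``; compounding it back over the interval recovers the
    interval probability exactly.  ``p_interval == 1`` maps to 1 for any
    interval length.
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    if not 0.0 <= p_interval <= 1.0:
        raise ValueError(f"interval probability {p_interval} outside [0, 1]")
    if p_interval == 1.0:
        return 1.0
    if n_cycles == 1:
        return float(p_interval)
    return 1.0 - (1.0 - p_interval) ** (1.0 / n_cycles)


def cycle_sequence(table: IntervalProbabilityTable, horizon_cycles: int) -> np.ndarray:
    """Per-cycle probabilities for the months the table covers (trimmed to horizon)."""
    out = np.zeros(min(table.last_month, horizon_cycles))
    for iv, p in table.entries:
        pm = interval_to_cycle_probability(p, iv.n_cycles)
        out[iv.start_month - 1 : iv.end_month] = pm
    return out


def _annualized(table: IntervalProbabilityTable, year: int) -> float:
    """Probability of the event within calendar year ``year`` of the model,
    conditional on being at risk at the year start (from the monthly sequence)."""
    seq = cycle_sequence(table, table.last_month)
    months = seq[(year - 1) * 12 : year * 12]
    if len(months) < 12:
        raise ValidationError(f"{table.event}/{table.arm}: year {year} not fully covered")
    return 1.0 - float(np.prod(1.0 - months))


def extrapolate_mortality(
    table: IntervalProbabilityTable,
    horizon_cycles: int,
    mode: str = "interval",
    fit_years: tuple[int, int] = (2, 5),
) -> tuple[np.ndarray, list[str]]:
    """Per-cycle mortality over the full horizon.

    Cycles within the observed window use the interval-converted monthly
    probabilities.  Later cycles follow a linear OLS trend fitted to the
    annualized probabilities of ``fit_years`` (default years 2-5), evaluated
    at each subsequent year and converted back to monthly, clamped to [0, 1].
    ``mode="cumulative"`` instead fits the line to the cumulative death
    fraction at the fit-year ends and differences it back to annual
    conditionals.
    """
    table.validate()
    if table.event != "mortality":
        raise ValueError("extrapolation applies to the mortality table")
    warnings: list[str] = []
    observed = cycle_sequence(table, horizon_cycles)
    out = np.zeros(horizon_cycles)
    n_obs = len(observed)
    out[:n_obs] = observed
    if horizon_cycles <= n_obs:
        return out[:horizon_cycles], warnings

    years = np.arange(fit_years[0], fit_years[1] + 1, dtype=float)
    annual = np.array([_annualized(table, int(y)) for y in years])
    first_missing_year = n_obs // 12 + 1  # observed window ends on a year boundary
    horizon_years = -(-horizon_cycles // 12)

    if mode == "interval":
        slope, intercept = np.polyfit(years, annual, 1)
        for y in range(first_missing_year, horizon_years + 1):
            p = intercept + slope * y
            if p > 1.0:
                warnings.append(
                    f"mortality/{table.arm}: fitted annual probability "
                    f"{p:.3f} at year {y} clamped to 1"
                )
            p = min(1.0, max(0.0, p))
            pm = interval_to_cycle_probability(p, 12)
            out[(y - 1) * 12 : min(y * 12, horizon_cycles)] = pm
    elif mode == "cumulative":
        surv = np.cumprod(1.0 - cycle_sequence(table, table.last_month))
        cum = np.array([1.0 - surv[int(y) * 12 - 1] for y in years])
        slope, intercept = np.polyfit(years, cum, 1)
        f_prev = cum[-1]
        for y in range(first_missing_year, horizon_years + 1):
            f = intercept + slope * y
            if f > 1.0:
                warnings.append(
                    f"mortality/{table.arm}: fitted cumulative fraction "
                    f"{f:.3f} at year {y} clamped to 1"
                )
            f = min(1.0, max(f_prev, f))
            p = 1.0 if f_prev >= 1.0 else (f - f_prev) / (1.0 - f_prev)
            pm = interval_to_cycle_probability(min(1.0, p), 12)
            out[(y - 1) * 12 : min(y * 12, horizon_cycles)] = pm
            f_prev = f
    else:
        raise ValueError(f"unknown extrapolation mode {mode!r}")
    if warnings:
        for w in warnings:
            logger.warning(w)
    return out, warnings


def extend_event_rates(
    table: IntervalProbabilityTable, horizon_cycles: int
) -> np.ndarray:
    """Per-cycle event probabilities, carrying the last band's converted
    monthly rate forward to the horizon."""
    if not table.entries:
        raise ValidationError(f"{table.event}/{table.arm}: empty table")
    observed = cycle_sequence(table, horizon_cycles)
    out = np.zeros(horizon_cycles)
    n_obs = len(observed)
    out[:n_obs] = observed
    if horizon_cycles > n_obs:
        last_iv, last_p = table.entries[-1]
        out[n_obs:] = interval_to_cycle_probability(last_p, last_iv.n_cycles)
    return out


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _read_events_csv(
    path: Path, risk_group: str, percent: bool
) -> dict[str, dict[str, IntervalProbabilityTable]]:
    rows_by_arm_event: dict[tuple[str, str], list[tuple[int, int, float]]] = {}
    with open(path, newline="") as f:
        for i, row in enumerate(csv.DictReader(f), start=2):
            if row["risk_group"] != risk_group:
                continue
            try:
                s, e = int(row["start_month"]), int(row["end_month"])
                p = float(row["probability"])
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"{path.name}:{i}: malformed row ({exc})") from exc
            if percent:
                p /= 100.0
            rows_by_arm_event.setdefault((row["arm"], row["event"]), []).append((s, e, p))
    if not rows_by_arm_event:
        raise ValidationError(f"{path.name}: no rows for risk group {risk_group!r}")
    events: dict[str, dict[str, IntervalProbabilityTable]] = {}
    for (arm, event), rows in rows_by_arm_event.items():
        rows.sort()
        table = IntervalProbabilityTable(
            event=event,
            arm=arm,
            entries=tuple((TimeInterval(s, e), p) for s, e, p in rows),
        )
        events.setdefault(arm, {})[event] = table
    return events


def _read_costs_csv(path: Path) -> CostTable:
    unit_costs: dict[str, float] = {}
    index_costs: dict[str, float] = {}
    with open(path, newline="") as f:
        for i, row in enumerate(csv.DictReader(f), start=2):
            try:
                c = float(row["euros"])
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"{path.name}:{i}: malformed row ({exc})") from exc
            item = row["item"]
            if item.endswith("_procedure"):
                index_costs[item[: -len("_procedure")]] = c
            else:
                unit_costs[item] = c
    index_costs.setdefault("medical", 0.0)  # medical therapy has no index procedure
    return CostTable(unit_costs=unit_costs, index_costs=index_costs)


def _read_utilities_csv(path: Path) -> UtilityTable:
    values: dict[tuple[int, bool, str], float] = {}
    with open(path, newline="") as f:
        for i, row in enumerate(csv.DictReader(f), start=2):
            state = row["state"]
            stroke = state.endswith("_stroke")
            nyha = int(state.removesuffix("_stroke").removeprefix("nyha"))
            values[(nyha, stroke, row["arm"])] = float(row["utility"])
    return UtilityTable(values=values)


def _read_nyha_csv(path: Path, horizon_cycles: int) -> dict[str, np.ndarray]:
    """Schema: arm,start_cycle,end_cycle,from_nyha,to_nyha,probability."""
    per_arm: dict[str, np.ndarray] = {}
    with open(path, newline="") as f:
        rows = list(csv.DictReader(f))
    arms = sorted({r["arm"] for r in rows})
    for arm in arms:
        m = np.zeros((horizon_cycles, 4, 4))
        for r in rows:
            if r["arm"] != arm:
                continue
            s, e = int(r["start_cycle"]), int(r["end_cycle"])
            e = min(e, horizon_cycles)
            m[s - 1 : e, int(r["from_nyha"]) - 1, int(r["to_nyha"]) - 1] = float(
                r["probability"]
            )
        per_arm[arm] = m
    return per_arm


def _deep_update(base: dict, overrides: Mapping) -> dict:
    for k, v in overrides.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def available_fixtures() -> list[str]:
    with open(DATA_DIR / "fixtures.yaml") as f:
        return sorted(yaml.safe_load(f)["fixtures"])


def load_parameter_set(
    fixture_name_or_paths: str | Mapping[str, object],
    overrides: Mapping | None = None,
) -> ParameterSet:
    """Build and validate a :class:`ParameterSet`.

    ``fixture_name_or_paths`` is either the name of a packaged fixture
    (``intermediate_base`` ... ``inoperable_micro``) or a mapping with keys
    ``risk_group``, ``events``, ``costs`` and optionally ``utilities``,
    ``nyha_transitions`` (CSV paths), ``percent``, ``settings``, ``scenario``
    and ``synthetic``.  ``overrides`` is deep-merged on top.

    Utility and NYHA-transition tables default to clearly-labelled synthetic
    stand-ins (see :mod:`tavicea.synthetic_data`) because the published
    supplementary tables carrying them are unavailable; pass CSV paths to use
    real values.
    """
    if isinstance(fixture_name_or_paths, str):
        with open(DATA_DIR / "fixtures.yaml") as f:
            registry = yaml.safe_load(f)["fixtures"]
        if fixture_name_or_paths not in registry:
            raise ValidationError(
                f"unknown fixture {fixture_name_or_paths!r}; "
                f"available: {', '.join(sorted(registry))}"
            )
        config = registry[fixture_name_or_paths]
        base_dir = DATA_DIR
    else:
        config = copy.deepcopy(dict(fixture_name_or_paths))
        base_dir = Path(config.pop("base_dir", "."))
    config = copy.deepcopy(config)
    if overrides:
        _deep_update(config, overrides)

    settings = ModelSettings(risk_group=config["risk_group"], **config.get("settings", {}))
    percent = bool(config.get("percent", False))

    def resolve(name: str) -> Path:
        p = Path(config[name])
        return p if p.is_absolute() else base_dir / p

    events = _read_events_csv(resolve("events"), settings.risk_group, percent)
    costs = _read_costs_csv(resolve("costs"))

    from . import synthetic_data  # deferred: synthetic_data builds on our types

    synth_cfg = synthetic_data.SyntheticConfig(**config.get("synthetic", {"seed": 0}))
    if "utilities" in config:
        utilities = _read_utilities_csv(resolve("utilities"))
    else:
        utilities = synthetic_data.generate_utilities(synth_cfg)
    if "nyha_transitions" in config:
        nyha = _read_nyha_csv(resolve("nyha_transitions"), max(settings.horizon_cycles, 1))
    else:
        nyha = {
            arm: synthetic_data.generate_nyha_transitions(
                synth_cfg, arm, max(settings.horizon_cycles, 1)
            )
            for arm in settings.arms
        }

    rehabilitation = Rehabilitation()
    scenario_index = None
    if "scenario" in config and config["scenario"]:
        sc = config["scenario"]
        scenario_index = {k: float(v) for k, v in sc.get("index_costs", {}).items()}
        reh = sc.get("rehabilitation", {})
        rehabilitation = Rehabilitation(
            uptake={k: float(v) for k, v in reh.get("uptake", {}).items()},
            unit_cost=None if reh.get("unit_cost") is None else float(reh["unit_cost"]),
        )

    params = ParameterSet(
        settings=settings,
        events=events,
        nyha_transitions=nyha,
        utilities=utilities,
        costs=costs,
        rehabilitation=rehabilitation,
        scenario_index_costs=scenario_index,
    )
    return params.validate()
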