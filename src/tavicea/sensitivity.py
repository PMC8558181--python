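"""One-way and probabilistic sensitivity analysis.

The one-way analysis (OWSA) perturbs each registered scalar input by a fixed
fraction (default +/-20%), reruns the full model, and ranks parameters by the
spread of the incremental cost-utility ratio (tornado ordering).  Interval
probabilities are perturbed as one multiplier per (arm, event) pair so a
tornado bar corresponds to a clinically meaningful driver ("mortality over
the time horizon", "risk of HF hospitalizations", ...), not to a single
table cell.

The probabilistic analysis (PSA) assigns Beta distributions to probabilities
and utilities and Normal distributions to tariff-based costs, draws all
parameters independently, and reruns both arms per draw.  Dispersion is not
reported in the source material; the default standard error is 20% of the
mean (matching the OWSA perturbation magnitude) and is configurable.  In the
default ``multiplier`` sampling mode one quantile is drawn per (arm, event)
pair and applied through each interval's own Beta, so the intervals of one
event move together; ``per_interval`` mode draws them independently.
"""
from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .economics import CEResult, compute_ce, run_arm, run_comparison
from .parameters import EVENT_CATEGORIES, ParameterSet

DEFAULT_SE_FRACTION = 0.2
DEFAULT_WTP_GRID = np.arange(0, 100_001, 1000)


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Distribution:
    """Sampling distribution for one scalar input."""

    kind: str  # beta | normal | point
    mean: float
    a: float = 0.0  # beta alpha / normal sd
    b: float = 0.0  # beta beta

    def ppf(self, u: float | np.ndarray) -> float | np.ndarray:
        if self.kind == "point":
            return self.mean if np.isscalar(u) else np.full_like(np.asarray(u, float), self.mean)
        if self.kind == "beta":
            return stats.beta.ppf(u, self.a, self.b)
        return stats.norm.ppf(u, loc=self.mean, scale=self.a)

    def sample(self, rng: np.random.Generator):
        return self.ppf(rng.uniform())


def make_distribution(
    mean: float, kind: str, dispersion_spec: dict | None = None
) -> Distribution:
    """Distribution parameters from a mean and a dispersion specification.

    ``dispersion_spec`` takes ``{"se": x}`` or ``{"se_frac": f}`` (default
    ``se_frac`` 0.2).  Beta uses method of moments,
    ``alpha = m (m(1-m)/v - 1)``; when the implied variance is infeasible
    (``v >= m(1-m)``) or the mean is degenerate the distribution falls back
    to a point mass with a warning.
    """
    spec = dispersion_spec or {}
    se = spec.get("se", abs(mean) * spec.get("se_frac", DEFAULT_SE_FRACTION))
    if kind == "normal":
        if se == 0:
            return Distribution("point", mean)
        return Distribution("normal", mean, a=se)
    if kind != "beta":
        raise ValueError(f"unknown distribution kind {kind!r}")
    if not 0.0 <= mean <= 1.0:
        raise ValueError(f"beta mean {mean} outside [0, 1]")
    if mean in (0.0, 1.0):
        _warnings.warn(f"beta with degenerate mean {mean}: using a point mass")
        return Distribution("point", mean)
    if se == 0:
        return Distribution("point", mean)
    v = se * se
    feasible = mean * (1.0 - mean)
    if v >= feasible:
        _warnings.warn(
            f"beta variance {v:.3g} exceeds feasible {feasible:.3g} "
            f"for mean {mean}: using a point mass"
        )
        return Distribution("point", mean)
    nu = feasible / v - 1.0
    return Distribution("beta", mean, a=mean * nu, b=(1.0 - mean) * nu)


# ---------------------------------------------------------------------------
# Parameter registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegisteredParameter:
    """One scalar knob the sensitivity analyses can move."""

    param_id: str
    group: str  # incidence | cost | utility
    arm: str | None
    key: object
    base_value: float


def build_registry(params: ParameterSet) -> list[RegisteredParameter]:
    """Scalar inputs: one incidence multiplier per (arm, event) pair, every
    unit and index procedure cost, every living-state utility."""
    reg: list[RegisteredParameter] = []
    for arm in params.settings.arms:
        for event in EVENT_CATEGORIES:
            probs = [p for _, p in params.events[arm][event].entries]
            reg.append(RegisteredParameter(
                param_id=f"incidence:{arm}:{event}", group="incidence",
                arm=arm, key=event, base_value=float(np.mean(probs)),
            ))
    for item in sorted(params.costs.unit_costs):
        reg.append(RegisteredParameter(
            param_id=f"cost:{item}", group="cost", arm=None, key=item,
            base_value=params.costs.unit_costs[item],
        ))
    for arm in sorted(params.costs.index_costs):
        reg.append(RegisteredParameter(
            param_id=f"cost:index:{arm}", group="cost", arm=arm, key=f"index:{arm}",
            base_value=params.costs.index_costs[arm],
        ))
    for (nyha, stroke, arm), u in sorted(params.utilities.values.items()):
        if arm not in params.settings.arms:
            continue
        state = f"nyha{nyha}" + ("_stroke" if stroke else "")
        reg.append(RegisteredParameter(
            param_id=f"utility:{arm}:{state}", group="utility", arm=arm,
            key=(nyha, stroke), base_value=u,
        ))
    return reg


def _apply(params: ParameterSet, values: dict[str, float]) -> tuple[ParameterSet, bool]:
    """New parameter set with registry entries multiplied/overridden.

    ``values`` maps param_id -> multiplier (incidence) or absolute value
    (cost, utility).  Returns (new set, whether any probability was clamped).
    """
    out = params.copy()
    clamped = False
    for pid, v in values.items():
        kind, _, rest = pid.partition(":")
        if kind == "incidence":
            arm, event = rest.split(":", 1)
            table = out.events[arm][event]
            raw = [p * v for _, p in table.entries]
            if any(p > 1.0 for p in raw):
                clamped = True
            out.events[arm][event] = table.with_probabilities(
                [min(1.0, max(0.0, p)) for p in raw]
            )
        elif kind == "cost":
            if rest.startswith("index:"):
                out.costs.index_costs[rest.split(":", 1)[1]] = max(0.0, v)
            else:
                out.costs.unit_costs[rest] = max(0.0, v)
        elif kind == "utility":
            arm, state = rest.split(":", 1)
            stroke = state.endswith("_stroke")
            nyha = int(state.removesuffix("_stroke").removeprefix("nyha"))
            if v > 1.0 or v < 0.0:
                clamped = True
            out.utilities.values[(nyha, stroke, arm)] = min(1.0, max(0.0, v))
        else:
            raise ValueError(f"unknown parameter id {pid!r}")
    return out, clamped


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class OWSAEntry:
    parameter: str
    low_value: float
    high_value: float
    icur_low: float | None
    icur_high: float | None
    range: float
    clamped: bool = False


def owsa(
    params: ParameterSet,
    perturbation: float = 0.20,
    top_n: int = 20,
    scenario_mode: bool = False,
) -> list[OWSAEntry]:
    """Tornado entries, sorted by descending ICUR range.

    Every registered input is set to (1 - perturbation) and (1 + perturbation)
    times its base value in turn (probabilities and utilities clamped to
    [0, 1]), the full model rerun, and the absolute ICUR spread recorded.
    """
    *_, base = run_comparison(params, scenario_mode=scenario_mode)
    if base.icur is None:
        raise ValueError("base-case ICUR undefined; tornado ranking needs a ratio")
    entries: list[OWSAEntry] = []
    for rp in build_registry(params):
        icurs: list[float | None] = []
        clamped = False
        for mult in (1.0 - perturbation, 1.0 + perturbation):
            if rp.group == "incidence":
                value: float = mult
            else:
                value = rp.base_value * mult
            perturbed, c = _apply(params, {rp.param_id: value})
            clamped |= c
            *_, ce = run_comparison(perturbed, scenario_mode=scenario_mode)
            icurs.append(ce.icur)
        low, high = icurs
        rng = abs(high - low) if (low is not None and high is not None) else math.inf
        entries.append(OWSAEntry(
            parameter=rp.param_id,
            low_value=rp.base_value * (1.0 - perturbation),
            high_value=rp.base_value * (1.0 + perturbation),
            icur_low=low, icur_high=high, range=rng, clamped=clamped,
        ))
    entries.sort(key=lambda e: -e.range)
    return entries[:top_n]


def tornado_frame(entries: list[OWSAEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "parameter": e.parameter, "low_icur": e.icur_low,
            "high_icur": e.icur_high, "range": e.range, "clamped": e.clamped,
        } for e in entries]
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    n_draws: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    delta_ly: np.ndarray
    seed: int | None
    base: CEResult
    distribution_spec: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for a in (self.delta_cost, self.delta_qaly, self.delta_ly):
            if len(a) != self.n_draws or not np.isfinite(a).all():
                raise ValueError("PSA draws must be finite, one per run")


def _sample_parameter_values(
    params: ParameterSet,
    rng: np.random.Generator,
    mode: str,
    se_frac: float,
    max_retries: int,
) -> ParameterSet:
    out = params.copy()
    spec = {"se_frac": se_frac}
    for arm in params.settings.arms:
        for event in EVENT_CATEGORIES:
            table = out.events[arm][event]
            u_common = rng.uniform()
            new = []
            for _, p in table.entries:
                dist = make_distribution(p, "beta", spec)
                u = u_common if mode == "multiplier" else rng.uniform()
                new.append(float(dist.ppf(u)))
            out.events[arm][event] = table.with_probabilities(new)
    for item, c in params.costs.unit_costs.items():
        out.costs.unit_costs[item] = _draw_nonnegative(
            make_distribution(c, "normal", spec), rng, max_retries
        )
    for arm, c in params.costs.index_costs.items():
        out.costs.index_costs[arm] = _draw_nonnegative(
            make_distribution(c, "normal", spec), rng, max_retries
        )
    # the stroke/no-stroke utilities of one class share a quantile so the
    # pair moves together and the decrement ordering survives sampling
    for arm in params.settings.arms:
        for nyha in range(1, 5):
            u_common = rng.uniform()
            for stroke in (False, True):
                base_u = params.utilities.values[(nyha, stroke, arm)]
                dist = make_distribution(base_u, "beta", spec)
                out.utilities.values[(nyha, stroke, arm)] = float(dist.ppf(u_common))
            ns = out.utilities.values[(nyha, False, arm)]
            if out.utilities.values[(nyha, True, arm)] > ns:
                out.utilities.values[(nyha, True, arm)] = ns
    return out


def _draw_nonnegative(
    dist: Distribution, rng: np.random.Generator, max_retries: int
) -> float:
    for _ in range(max_retries):
        v = float(dist.sample(rng))
        if v >= 0.0:
            return v
    _warnings.warn(f"{max_retries} negative draws for mean {dist.mean}; clamping to 0")
    return 0.0


def psa(
    params: ParameterSet,
    n_draws: int = 1000,
    seed: int | None = None,
    mode: str = "multiplier",
    se_frac: float = DEFAULT_SE_FRACTION,
    max_retries: int = 100,
    scenario_mode: bool = False,
) -> PSAResult:
    """Monte-Carlo parameter uncertainty: per draw, sample every registered
    input, rerun both arms, and record the incremental cost/QALY/LY triple.
    Fully reproducible from ``seed``."""
    if mode not in ("multiplier", "per_interval"):
        raise ValueError(f"unknown PSA sampling mode {mode!r}")
    rng = np.random.default_rng(seed)
    *_, base = run_comparison(params, scenario_mode=scenario_mode)
    dc = np.empty(n_draws)
    dq = np.empty(n_draws)
    dl = np.empty(n_draws)
    iv_arm, cp_arm = params.settings.arms
    for i in range(n_draws):
        drawn = _sample_parameter_values(params, rng, mode, se_frac, max_retries)
        a = run_arm(drawn, iv_arm, scenario_mode=scenario_mode)
        b = run_arm(drawn, cp_arm, scenario_mode=scenario_mode)
        dc[i] = a.discounted_cost - b.discounted_cost
        dq[i] = a.discounted_qaly - b.discounted_qaly
        dl[i] = a.discounted_ly - b.discounted_ly
    result = PSAResult(
        n_draws=n_draws, delta_cost=dc, delta_qaly=dq, delta_ly=dl,
        seed=seed, base=base,
        distribution_spec={
            "incidence": "beta", "utility": "beta", "cost": "normal",
            "se": f"{se_frac:.0%} of mean", "mode": mode,
        },
    )
    result.validate()
    return result


# ---------------------------------------------------------------------------
# Acceptability curves and CE plane
# ---------------------------------------------------------------------------

@dataclass
class CEACCurve:
    wtp: np.ndarray
    probability: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.wtp, "probability": self.probability})


def ceac(psa_result: PSAResult, wtp_grid: np.ndarray | None = None) -> CEACCurve:
    """Probability of a positive net monetary benefit
    ``lambda * dQALY - dCost`` at each willingness-to-pay value."""
    if psa_result.n_draws == 0:
        raise ValueError("CEAC needs a non-empty draw set")
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    nmb = grid[:, None] * psa_result.delta_qaly[None, :] - psa_result.delta_cost[None, :]
    return CEACCurve(wtp=grid, probability=(nmb > 0).mean(axis=1))


def ce_plane_export(psa_result: PSAResult) -> pd.DataFrame:
    """One row per draw: incremental effect, incremental cost, CE-plane
    quadrant (NE = costlier & more effective, etc.)."""
    if psa_result.n_draws == 0:
        raise ValueError("CE plane needs a non-empty draw set")
    dq, dc = psa_result.delta_qaly, psa_result.delta_cost
    quadrant = np.where(
        dq >= 0, np.where(dc >= 0, "NE", "SE"), np.where(dc >= 0, "NW", "SW")
    )
    return pd.DataFrame({
        "draw": np.arange(psa_result.n_draws),
        "delta_qaly": dq,
        "delta_cost": dc,
        "quadrant": quadrant,
    })
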