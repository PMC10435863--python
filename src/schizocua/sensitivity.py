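"""Sensitivity and scenario analyses.

One-way (tornado) analysis over parameter bounds, probabilistic sensitivity
analysis by Monte Carlo over method-of-moments Beta/Gamma fits,
cost-effectiveness acceptability curves, the three scenario sweeps (drug
price, hospitalization cost level, time horizon) and the cumulative-horizon
ICER-by-cycle series.

Published ranges are read as 95% intervals, so ``sd = (high - low) / 3.92``.
PSA draws are shared across arms for shared parameters (hospitalization,
outpatient costs, utilities, and drug costs reused by another arm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .economics import compare
from .markov import StrategyResult, run_cohort
from .parameters import (
    ArmParameters,
    ConfigurationError,
    CostParameter,
    CycleProbability,
    DomainError,
    ModelConfig,
    UtilityWeight,
)

__all__ = [
    "ParameterDistribution",
    "UncertainParameter",
    "TornadoEntry",
    "PsaSample",
    "PsaResult",
    "CeacPoint",
    "ScenarioGrid",
    "fit_beta",
    "fit_gamma",
    "uncertain_parameters",
    "tornado",
    "run_psa",
    "ceac",
    "scenario_sweep",
    "icer_by_cycle",
]

RANGE_TO_SD = 3.92  # 95% interval width in standard deviations


# ---------------------------------------------------------------------------
# distribution fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterDistribution:
    """A PSA-ready description of one uncertain parameter."""

    parameter_id: str
    family: str  # {"beta", "gamma", "fixed"}
    mean: float
    low: float
    high: float
    fitted: Mapping[str, float] = field(default_factory=dict)

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return self.mean
        if self.family == "beta":
            return float(rng.beta(self.fitted["alpha"], self.fitted["beta"]))
        if self.family == "gamma":
            return float(rng.gamma(self.fitted["shape"], self.fitted["scale"]))
        raise DomainError(f"unknown distribution family {self.family!r}")


def fit_beta(mean: float, bounds: tuple[float, float],
             parameter_id: str = "") -> ParameterDistribution:
    """Method-of-moments Beta fit with sd = (high - low) / 3.92.

    ``nu = mean (1 - mean) / sd^2 - 1``; ``alpha = mean nu``;
    ``beta = (1 - mean) nu``.  Infeasible moments (variance at or above
    ``mean (1 - mean)``) raise.
    """
    low, high = bounds
    if not 0.0 < mean < 1.0:
        raise DomainError(f"beta mean must be in (0, 1), got {mean}")
    if not low < high:
        raise DomainError(f"bounds must satisfy low < high, got {bounds}")
    sd = (high - low) / RANGE_TO_SD
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0.0:
        raise DomainError(
            f"infeasible moments for beta fit: variance {sd**2} >= "
            f"mean(1-mean) = {mean * (1.0 - mean)}"
        )
    return ParameterDistribution(
        parameter_id=parameter_id, family="beta", mean=mean, low=low, high=high,
        fitted={"alpha": mean * nu, "beta": (1.0 - mean) * nu},
    )


def fit_gamma(mean: float, bounds: tuple[float, float],
              parameter_id: str = "") -> ParameterDistribution:
    """Method-of-moments Gamma fit: shape = mean^2/sd^2, scale = sd^2/mean."""
    low, high = bounds
    if mean <= 0.0:
        raise DomainError(f"gamma mean must be > 0, got {mean}")
    if not low < high:
        raise DomainError(f"bounds must satisfy low < high, got {bounds}")
    sd = (high - low) / RANGE_TO_SD
    return ParameterDistribution(
        parameter_id=parameter_id, family="gamma", mean=mean, low=low, high=high,
        fitted={"shape": mean**2 / sd**2, "scale": sd**2 / mean},
    )


# ---------------------------------------------------------------------------
# the uncertain-parameter registry
# ---------------------------------------------------------------------------

Arms = Mapping[str, ArmParameters]
ApplyFn = Callable[[dict, ModelConfig, float], tuple[dict, ModelConfig]]


@dataclass(frozen=True)
class UncertainParameter:
    """One uncertain model input: its moments and how to write a new value
    back into a parameter set."""

    parameter_id: str
    kind: str  # {"probability", "cost", "utility", "rate"}
    mean: float
    low: float
    high: float
    family: str
    apply: ApplyFn

    def distribution(self) -> ParameterDistribution:
        if self.family == "fixed" or self.low == self.high:
            return ParameterDistribution(self.parameter_id, "fixed",
                                         self.mean, self.low, self.high)
        if self.family == "beta":
            return fit_beta(self.mean, (self.low, self.high), self.parameter_id)
        if self.family == "gamma":
            return fit_gamma(self.mean, (self.low, self.high), self.parameter_id)
        raise DomainError(f"unknown family {self.family!r}")


def _widen_prob(p: CycleProbability, v: float) -> CycleProbability:
    return replace(p, value=v, low=min(p.low, v), high=max(p.high, v))


def _widen_cost(c: CostParameter, v: float) -> CostParameter:
    return replace(c, mean=v, low=min(c.low, v), high=max(c.high, v))


def _prob_apply(arm_name: str, field_name: str) -> ApplyFn:
    def apply(arms: dict, config: ModelConfig, v: float):
        arm = arms[arm_name]
        new = replace(arm, **{field_name: _widen_prob(getattr(arm, field_name), v)})
        out = dict(arms)
        out[arm_name] = new
        return out, config

    return apply


def _drug_cost_apply(targets: Sequence[tuple[str, str]]) -> ApplyFn:
    def apply(arms: dict, config: ModelConfig, v: float):
        out = dict(arms)
        for arm_name, field_name in targets:
            arm = out[arm_name]
            out[arm_name] = replace(
                arm, **{field_name: _widen_cost(getattr(arm, field_name), v)})
        return out, config

    return apply


def _shared_cost_apply(field_name: str) -> ApplyFn:
    def apply(arms: dict, config: ModelConfig, v: float):
        sc = config.shared_costs
        new_sc = replace(sc, **{field_name: _widen_cost(getattr(sc, field_name), v)})
        return dict(arms), replace(config, shared_costs=new_sc)

    return apply


def _utility_apply(state: str) -> ApplyFn:
    def apply(arms: dict, config: ModelConfig, v: float):
        u = config.utilities[state]
        new_u = replace(u, per_cycle_weight=v, low=min(u.low, v), high=max(u.high, v))
        utilities = dict(config.utilities)
        utilities[state] = new_u
        return dict(arms), replace(config, utilities=utilities)

    return apply


def _discount_apply(arms: dict, config: ModelConfig, v: float):
    return dict(arms), replace(config, annual_discount_rate=v)


_PROB_FIELDS = ("p_disc_nonstable", "p_disc_stable", "p_relapse_stable",
                "p_relapse_nonadherent", "p_hosp_nonstable")


def uncertain_parameters(
    arms: Arms, config: ModelConfig, include_discount: bool = False
) -> list[UncertainParameter]:
    """Enumerate every uncertain input of a parameter set in a fixed order.

    Drug-cost parameters are deduplicated across arms: an arm whose
    non-stable drug cost equals another arm's (stable) drug cost shares that
    arm's cost parameter, so one PSA draw moves both (e.g. the 3-monthly
    arm's non-stable state reuses the 1-monthly product's cost).

    The discount rate (swept 0-8% in one-way analysis, never in PSA) is
    appended only when ``include_discount`` is set.
    """
    out: list[UncertainParameter] = []
    for arm_name, arm in arms.items():
        for field_name in _PROB_FIELDS:
            p: CycleProbability = getattr(arm, field_name)
            out.append(UncertainParameter(
                parameter_id=f"{arm_name}.{field_name}", kind="probability",
                mean=p.value, low=p.low, high=min(p.high, 1.0),
                family=p.distribution_family,
                apply=_prob_apply(arm_name, field_name),
            ))

    arm_names = list(arms)
    for arm_name in arm_names:
        stable = arms[arm_name].drug_cost_cycle_stable
        targets: list[tuple[str, str]] = [(arm_name, "drug_cost_cycle_stable")]
        for other in arm_names:
            nonstable = arms[other].drug_cost_cycle_nonstable
            own_stable = arms[other].drug_cost_cycle_stable
            if nonstable.mean == stable.mean and (
                other == arm_name or nonstable.mean != own_stable.mean
            ):
                targets.append((other, "drug_cost_cycle_nonstable"))
        out.append(UncertainParameter(
            parameter_id=f"cost.{arm_name}", kind="cost",
            mean=stable.mean, low=stable.low, high=stable.high,
            family=stable.distribution_family,
            apply=_drug_cost_apply(targets),
        ))

    sc = config.shared_costs
    for name in ("hospitalization", "outpatient_stable", "outpatient_nonstable"):
        c: CostParameter = getattr(sc, name)
        out.append(UncertainParameter(
            parameter_id=f"cost.{name}", kind="cost",
            mean=c.mean, low=c.low, high=c.high, family=c.distribution_family,
            apply=_shared_cost_apply(name),
        ))

    for state in sorted(config.utilities):
        u: UtilityWeight = config.utilities[state]
        out.append(UncertainParameter(
            parameter_id=f"utility.{state}", kind="utility",
            mean=u.per_cycle_weight, low=u.low, high=u.high,
            family=u.distribution_family,
            apply=_utility_apply(state),
        ))

    if include_discount:
        out.append(UncertainParameter(
            parameter_id="discount_rate", kind="rate",
            mean=config.annual_discount_rate, low=0.0, high=0.08, family="fixed",
            apply=_discount_apply,
        ))
    return out


# ---------------------------------------------------------------------------
# one-way (tornado) analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    parameter_id: str
    icer_low: float
    icer_high: float
    width: float
    flagged: bool = False  # a bound invalidated the model or the ICER


def _icer_ratio(intervention: StrategyResult, comparator: StrategyResult) -> float:
    """Raw incremental ratio for sensitivity series; NaN when effects tie."""
    dq = intervention.total_qaly - comparator.total_qaly
    if dq == 0.0:
        return math.nan
    return (intervention.total_cost - comparator.total_cost) / dq


def _run_pair(arms: Arms, config: ModelConfig,
              comparison: tuple[str, str]) -> float:
    intervention, comparator = comparison
    _, res_i = run_cohort(arms[intervention], config)
    _, res_c = run_cohort(arms[comparator], config)
    return _icer_ratio(res_i, res_c)


def tornado(
    arms: Arms, config: ModelConfig, comparison: tuple[str, str]
) -> list[TornadoEntry]:
    """One-way sensitivity analysis of the ICER for one pairwise comparison.

    Each uncertain parameter (plus the discount rate over 0-8%) is set to
    its lower and upper bound in turn with everything else at base; entries
    are sorted by induced ICER width, descending, ties broken by id.
    """
    entries: list[TornadoEntry] = []
    for param in uncertain_parameters(arms, config, include_discount=True):
        icers = []
        flagged = False
        for bound in (param.low, param.high):
            try:
                new_arms, new_config = param.apply(dict(arms), config, bound)
                icer = _run_pair(new_arms, new_config, comparison)
            except (ConfigurationError, DomainError):
                icer, flagged = math.nan, True
            if math.isnan(icer):
                flagged = True
            icers.append(icer)
        width = abs(icers[1] - icers[0]) if not flagged else math.nan
        entries.append(TornadoEntry(param.parameter_id, icers[0], icers[1],
                                    0.0 if math.isnan(width) else width, flagged))
    entries.sort(key=lambda e: (-e.width, e.parameter_id))
    return entries


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsaSample:
    iteration: int
    costs: Mapping[str, float]  # arm -> discounted cost
    qalys: Mapping[str, float]
    delta_costs: Mapping[str, float]  # "ARM_vs_COMPARATOR" -> increment
    delta_qalys: Mapping[str, float]


@dataclass(frozen=True)
class PsaResult:
    samples: tuple[PsaSample, ...]
    n_redraws: int
    seed: int
    comparator: str
    draws: tuple[Mapping[str, float], ...] = ()  # per-iteration parameter draws


_MAX_REDRAWS = 1000


def run_psa(
    arms: Arms,
    config: ModelConfig,
    n_iterations: int,
    seed: int,
    comparator: str = "ER",
    distributions: Mapping[str, ParameterDistribution] | None = None,
    record_draws: bool = False,
) -> PsaResult:
    """Monte Carlo propagation of parameter uncertainty.

    Every uncertain parameter is drawn independently from its fitted
    distribution each iteration (Beta for probabilities and utilities,
    Gamma for costs); shared parameters use a single draw across arms.  A
    draw that makes an arm's conditional transition mass exceed 1 triggers
    a redraw of that parameter only, counted in ``n_redraws``.

    ``distributions`` overrides the default fits by parameter id (e.g. to
    force everything ``fixed``, which must reproduce the base case exactly).
    """
    if n_iterations < 1:
        raise DomainError("n_iterations must be >= 1")
    if comparator not in arms:
        raise DomainError(f"unknown comparator arm {comparator!r}")
    params = uncertain_parameters(arms, config, include_discount=False)
    dists = {p.parameter_id: p.distribution() for p in params}
    if distributions:
        dists.update(distributions)

    rng = np.random.default_rng(seed)
    samples: list[PsaSample] = []
    all_draws: list[dict[str, float]] = []
    n_redraws = 0

    for it in range(n_iterations):
        cur_arms, cur_config = dict(arms), config
        drawn: dict[str, float] = {}
        for param in params:
            v = dists[param.parameter_id].sample(rng)
            cur_arms, cur_config = param.apply(cur_arms, cur_config, v)
            drawn[param.parameter_id] = v

        # redraw any stable-state relapse draw that breaks feasibility
        for arm_name in cur_arms:
            attempts = 0
            while (cur_arms[arm_name].p_disc_stable.value
                   + cur_arms[arm_name].p_relapse_stable.value) > 1.0:
                pid = f"{arm_name}.p_relapse_stable"
                param = next(p for p in params if p.parameter_id == pid)
                v = dists[pid].sample(rng)
                cur_arms, cur_config = param.apply(cur_arms, cur_config, v)
                drawn[pid] = v
                n_redraws += 1
                attempts += 1
                if attempts > _MAX_REDRAWS:
                    raise ConfigurationError(
                        f"{arm_name}: could not draw a feasible relapse "
                        f"probability after {_MAX_REDRAWS} redraws")

        costs: dict[str, float] = {}
        qalys: dict[str, float] = {}
        for arm_name, arm in cur_arms.items():
            _, res = run_cohort(arm, cur_config)
            costs[arm_name] = res.total_cost
            qalys[arm_name] = res.total_qaly
        delta_costs = {f"{a}_vs_{comparator}": costs[a] - costs[comparator]
                       for a in cur_arms if a != comparator}
        delta_qalys = {f"{a}_vs_{comparator}": qalys[a] - qalys[comparator]
                       for a in cur_arms if a != comparator}
        samples.append(PsaSample(it, costs, qalys, delta_costs, delta_qalys))
        if record_draws:
            all_draws.append(drawn)

    return PsaResult(tuple(samples), n_redraws, seed, comparator, tuple(all_draws))


@dataclass(frozen=True)
class CeacPoint:
    wtp: float
    probability_cost_effective: float


def ceac(
    samples: Sequence[PsaSample],
    wtp_grid: Sequence[float],
    comparison: str,
) -> list[CeacPoint]:
    """Acceptability curve: at each threshold, the fraction of iterations in
    which the intervention's net monetary benefit strictly exceeds the
    comparator's (ties count for the comparator)."""
    if not samples or len(wtp_grid) == 0:
        raise DomainError("samples and wtp_grid must be non-empty")
    dc = np.array([s.delta_costs[comparison] for s in samples])
    dq = np.array([s.delta_qalys[comparison] for s in samples])
    points = []
    for wtp in wtp_grid:
        prob = float(np.mean(wtp * dq - dc > 0.0))
        points.append(CeacPoint(float(wtp), prob))
    return points


# ---------------------------------------------------------------------------
# scenario analyses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioGrid:
    axis_name: str
    axis_values: tuple[float, ...]
    icer_series: Mapping[str, tuple[float, ...]]


DEFAULT_PRICE_MULTIPLIERS = (1.0, 0.89, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)
DEFAULT_HOSPITALIZATION_MULTIPLIERS = (1.2, 1.0, 0.8, 0.6, 0.4, 0.2)
DEFAULT_HORIZONS_YEARS = (1.0, 5.0, 10.0, 20.0, 30.0, 40.0)


def _scale_drug_costs(arms: Arms, multiplier: float,
                      only_arms: Sequence[str] | None) -> dict:
    out = {}
    for name, arm in arms.items():
        if only_arms is not None and name not in only_arms:
            out[name] = arm
            continue
        out[name] = replace(
            arm,
            drug_cost_cycle_stable=_widen_cost(
                arm.drug_cost_cycle_stable, arm.drug_cost_cycle_stable.mean * multiplier),
            drug_cost_cycle_nonstable=_widen_cost(
                arm.drug_cost_cycle_nonstable,
                arm.drug_cost_cycle_nonstable.mean * multiplier),
        )
    return out


def scenario_sweep(
    arms: Arms,
    config: ModelConfig,
    axis_name: str,
    axis_values: Sequence[float] | None = None,
    comparator: str = "ER",
    price_only_arms: Sequence[str] | None = None,
) -> ScenarioGrid:
    """Re-run the pairwise comparisons along one scenario axis.

    Axes: ``price_multiplier`` (scales per-cycle drug costs; all arms by
    default, or only ``price_only_arms``), ``hospitalization_multiplier``
    (scales the admission cost), and ``horizon_years``.  Each grid includes
    the base case as a consistency anchor by default.
    """
    if axis_name == "price_multiplier":
        values = tuple(axis_values) if axis_values is not None else DEFAULT_PRICE_MULTIPLIERS
    elif axis_name == "hospitalization_multiplier":
        values = tuple(axis_values) if axis_values is not None else DEFAULT_HOSPITALIZATION_MULTIPLIERS
    elif axis_name == "horizon_years":
        values = tuple(axis_values) if axis_values is not None else DEFAULT_HORIZONS_YEARS
    else:
        raise DomainError(f"unknown scenario axis {axis_name!r}")

    comparisons = [f"{a}_vs_{comparator}" for a in arms if a != comparator]
    series: dict[str, list[float]] = {c: [] for c in comparisons}

    for v in values:
        cur_arms, cur_config = dict(arms), config
        if axis_name == "price_multiplier":
            if v <= 0:
                raise DomainError(f"price multiplier must be > 0, got {v}")
            cur_arms = _scale_drug_costs(arms, v, price_only_arms)
        elif axis_name == "hospitalization_multiplier":
            if v <= 0:
                raise DomainError(f"hospitalization multiplier must be > 0, got {v}")
            sc = config.shared_costs
            cur_config = replace(config, shared_costs=replace(
                sc, hospitalization=_widen_cost(sc.hospitalization,
                                                sc.hospitalization.mean * v)))
        else:
            cur_config = replace(config, horizon_years=float(v))

        results = {name: run_cohort(arm, cur_config)[1]
                   for name, arm in cur_arms.items()}
        for a in arms:
            if a == comparator:
                continue
            series[f"{a}_vs_{comparator}"].append(
                _icer_ratio(results[a], results[comparator]))

    return ScenarioGrid(axis_name, values,
                        {c: tuple(s) for c, s in series.items()})


def icer_by_cycle(
    arms: Arms, config: ModelConfig, max_cycles: int, comparator: str = "ER"
) -> ScenarioGrid:
    """Cumulative-horizon ICER after each cycle 1..max_cycles.

    The truncated-horizon model is a prefix of the full trace (half-cycle
    correction and discounting depend only on the cycle index), so the whole
    series comes from one run per arm via cumulative sums.
    """
    if max_cycles < 1:
        raise DomainError("max_cycles must be >= 1")
    full = config.with_horizon_cycles(max_cycles)
    cum_cost: dict[str, np.ndarray] = {}
    cum_qaly: dict[str, np.ndarray] = {}
    for name, arm in arms.items():
        _, res = run_cohort(arm, full)
        cum_cost[name] = np.cumsum(res.per_cycle_costs)
        cum_qaly[name] = np.cumsum(res.per_cycle_qalys)

    series = {}
    for a in arms:
        if a == comparator:
            continue
        dq = cum_qaly[a] - cum_qaly[comparator]
        dc = cum_cost[a] - cum_cost[comparator]
        with np.errstate(divide="ignore", invalid="ignore"):
            icers = np.where(dq != 0.0, dc / dq, np.nan)
        series[f"{a}_vs_{comparator}"] = tuple(float(x) for x in icers)

    return ScenarioGrid("cycle_count", tuple(float(k) for k in range(1, max_cycles + 1)),
                        series)
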