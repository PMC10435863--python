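"""Random and degenerate parameter sets for property testing.

Synthetic sets sample the valid parameter space uniformly (not from the PSA
distributions -- the goal is coverage, not mimicry) and always pass
:func:`schizocua.parameters.validate`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .parameters import (
    ArmParameters,
    ConfigurationError,
    CostParameter,
    CycleProbability,
    DomainError,
    ModelConfig,
    MortalityBand,
    MortalityTable,
    SharedCosts,
    UtilityWeight,
    load_reference_parameters,
    validate,
)

__all__ = ["SyntheticSpec", "random_parameter_set", "degenerate_fixture",
           "perturbed_reference"]

_MAX_REJECTIONS = 1000


@dataclass(frozen=True)
class SyntheticSpec:
    """Sampling ranges for one random parameter set."""

    seed: int = 0
    n_arms: int = 3
    probability_range: tuple[float, float] = (0.0, 0.5)
    cost_range: tuple[float, float] = (10.0, 2000.0)
    utility_range: tuple[float, float] = (0.05, 0.95)
    horizon_years: float = 5.0
    mortality_level: float = 0.01  # annual probability scale


def _rand_prob(rng: np.random.Generator, lo: float, hi: float) -> CycleProbability:
    v = float(rng.uniform(lo, hi))
    spread = 0.1 * v
    return CycleProbability(v, max(0.0, v - spread), min(1.0, v + spread), "beta")


def _rand_cost(rng: np.random.Generator, lo: float, hi: float,
               basis: str = "per_cycle") -> CostParameter:
    v = float(rng.uniform(lo, hi))
    return CostParameter(v, 0.8 * v, 1.2 * v, "gamma", basis)


def random_parameter_set(spec: SyntheticSpec) -> tuple[dict[str, ArmParameters], ModelConfig]:
    """Draw a complete valid parameter set; seeded and reproducible.

    Draws violating conditional-mass feasibility (stable-state
    discontinuation plus relapse above 1) are rejected and redrawn, with a
    bounded number of attempts.
    """
    lo, hi = spec.probability_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise DomainError(f"probability_range {spec.probability_range} invalid")
    rng = np.random.default_rng(spec.seed)

    arms: dict[str, ArmParameters] = {}
    for i in range(spec.n_arms):
        name = f"ARM{i}"
        for attempt in range(_MAX_REJECTIONS + 1):
            p_disc_stable = _rand_prob(rng, lo, hi)
            p_relapse_stable = _rand_prob(rng, lo, hi)
            if p_disc_stable.value + p_relapse_stable.value <= 1.0:
                break
            if attempt == _MAX_REJECTIONS:
                raise ConfigurationError(
                    f"could not draw feasible stable-state transitions within "
                    f"{_MAX_REJECTIONS} attempts for range {spec.probability_range}")
        drug = _rand_cost(rng, *spec.cost_range)
        arms[name] = ArmParameters(
            arm_name=name,
            p_disc_nonstable=_rand_prob(rng, lo, hi),
            p_disc_stable=p_disc_stable,
            p_relapse_stable=p_relapse_stable,
            p_relapse_nonadherent=_rand_prob(rng, lo, hi),
            p_hosp_nonstable=_rand_prob(rng, lo, hi),
            drug_cost_cycle_stable=drug,
            drug_cost_cycle_nonstable=drug,
        )

    u_lo, u_hi = spec.utility_range
    u_stable = float(rng.uniform(u_lo, u_hi))
    u_non = float(rng.uniform(u_lo, min(u_hi, u_stable)))
    mort = min(0.99, max(1e-6, float(rng.uniform(0.5, 1.5)) * spec.mortality_level))
    config = ModelConfig(
        horizon_years=spec.horizon_years,
        cycle_months=3.0,
        annual_discount_rate=float(rng.uniform(0.0, 0.08)),
        start_age=38.0,
        utilities={
            "stable": UtilityWeight(u_stable, max(0.0, 0.9 * u_stable),
                                    min(1.0, 1.1 * u_stable), "beta"),
            "non_stable": UtilityWeight(u_non, max(0.0, 0.9 * u_non),
                                        min(1.0, 1.1 * u_non), "beta"),
        },
        shared_costs=SharedCosts(
            hospitalization=_rand_cost(rng, *spec.cost_range, basis="per_admission"),
            outpatient_stable=_rand_cost(rng, *spec.cost_range),
            outpatient_nonstable=_rand_cost(rng, *spec.cost_range),
        ),
        mortality=MortalityTable(bands=(MortalityBand(0.0, 120.0, mort),)),
        relapse_hospitalization_policy="never",
    )
    violations = validate(arms, config)
    if violations:  # pragma: no cover - contract: generated sets are valid
        raise ConfigurationError("; ".join(violations))
    return arms, config


def degenerate_fixture(kind: str) -> tuple[dict[str, ArmParameters], ModelConfig]:
    """Analytically tractable variants of the reference parameter set.

    ``no_relapse``: both relapse probabilities zero in every arm.
    ``no_mortality``: death probability zero at every age.
    ``immediate_death``: certain death in the first cycle.
    ``zero_discount``: discount rate zero.
    ``single_cycle``: a one-cycle horizon.
    """
    arms, config = load_reference_parameters()
    zero = CycleProbability(0.0, 0.0, 0.0, "fixed")
    if kind == "no_relapse":
        arms = {name: replace(arm, p_relapse_stable=zero, p_relapse_nonadherent=zero)
                for name, arm in arms.items()}
    elif kind == "no_mortality":
        config = replace(config, mortality=MortalityTable(
            bands=(MortalityBand(0.0, 120.0, 0.0),)))
    elif kind == "immediate_death":
        config = replace(config, mortality=MortalityTable(
            bands=(MortalityBand(0.0, 120.0, 1.0),)))
    elif kind == "zero_discount":
        config = replace(config, annual_discount_rate=0.0)
    elif kind == "single_cycle":
        config = config.with_horizon_cycles(1)
    else:
        raise DomainError(f"unknown degenerate fixture kind {kind!r}")
    return arms, config


def _clamp_prob(p: CycleProbability, factor: float) -> CycleProbability:
    v = min(1.0, max(0.0, p.value * factor))
    return CycleProbability(v, min(p.low, v), max(min(p.high, 1.0), v),
                            p.distribution_family)


def _scale_cost(c: CostParameter, factor: float) -> CostParameter:
    v = c.mean * factor
    return CostParameter(v, min(c.low, v), max(c.high, v),
                         c.distribution_family, c.basis)


def perturbed_reference(
    epsilon: float, seed: int
) -> tuple[dict[str, ArmParameters], ModelConfig]:
    """Reference set with every uncertain parameter jittered by an
    independent uniform factor in ``[1 - epsilon, 1 + epsilon]``, re-clamped
    to valid bounds.  ``epsilon = 0`` returns the reference set unchanged."""
    if not 0.0 <= epsilon <= 0.5:
        raise DomainError(f"epsilon must be in [0, 0.5], got {epsilon}")
    arms, config = load_reference_parameters()
    if epsilon == 0.0:
        return arms, config
    rng = np.random.default_rng(seed)

    def f() -> float:
        return float(rng.uniform(1.0 - epsilon, 1.0 + epsilon))

    new_arms: dict[str, ArmParameters] = {}
    for name, arm in arms.items():
        p_disc_stable = _clamp_prob(arm.p_disc_stable, f())
        p_relapse_stable = _clamp_prob(arm.p_relapse_stable, f())
        if p_disc_stable.value + p_relapse_stable.value > 1.0:
            p_relapse_stable = _clamp_prob(
                p_relapse_stable, (1.0 - p_disc_stable.value) / p_relapse_stable.value)
        new_arms[name] = replace(
            arm,
            p_disc_nonstable=_clamp_prob(arm.p_disc_nonstable, f()),
            p_disc_stable=p_disc_stable,
            p_relapse_stable=p_relapse_stable,
            p_relapse_nonadherent=_clamp_prob(arm.p_relapse_nonadherent, f()),
            p_hosp_nonstable=_clamp_prob(arm.p_hosp_nonstable, f()),
            drug_cost_cycle_stable=_scale_cost(arm.drug_cost_cycle_stable, f()),
            drug_cost_cycle_nonstable=_scale_cost(arm.drug_cost_cycle_nonstable, f()),
        )

    sc = config.shared_costs
    utilities = {}
    for state, u in config.utilities.items():
        v = min(1.0, u.per_cycle_weight * f())
        utilities[state] = UtilityWeight(v, min(u.low, v), max(min(u.high, 1.0), v),
                                         u.distribution_family)
    config = replace(
        config,
        utilities=utilities,
        shared_costs=SharedCosts(
            hospitalization=_scale_cost(sc.hospitalization, f()),
            outpatient_stable=_scale_cost(sc.outpatient_stable, f()),
            outpatient_nonstable=_scale_cost(sc.outpatient_nonstable, f()),
        ),
    )
    violations = validate(new_arms, config)
    if violations:  # pragma: no cover
        raise ConfigurationError("; ".join(violations))
    return new_arms, config
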