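"""Model inputs: domain types, rate conversions, the reference parameter set.

All probabilities are per model cycle, all costs are 2022 USD, and utilities
are QALY weights accrued per cycle of full state occupancy.  The reference
parameter set embedded here drives the base case; alternative parameter sets
with the same shape can be loaded from YAML (see :mod:`schizocua.config_io`)
or generated synthetically (see :mod:`schizocua.synthetic`).

A deliberate interpretation, recorded here because it changes every result:
the printed state utilities (0.23 stable, 0.15 non-stable) are treated as
per-3-month-cycle QALY weights, i.e. annual utilities of 0.92 and 0.60.
Scaling them by cycle length in years instead would shrink total QALYs by a
factor of four and is not what this package does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "RateObservation",
    "CycleProbability",
    "CostParameter",
    "UtilityWeight",
    "MortalityBand",
    "MortalityTable",
    "SharedCosts",
    "ArmParameters",
    "ModelConfig",
    "rate_to_cycle_prob",
    "cycle_prob_to_rate",
    "annual_prob_to_cycle",
    "mortality_for_age",
    "drug_cost_per_cycle",
    "load_reference_parameters",
    "reference_parameters_frame",
    "validate",
    "SOURCE_EVENT_RATES",
    "PRICE_PER_MG",
    "MEAN_DAILY_DOSE_MG",
]

ARM_NAMES = ("PP1M", "PP3M", "ER")


class DomainError(ValueError):
    """An operation was called with an argument outside its domain."""


class ConfigurationError(ValueError):
    """A parameter set cannot be used to construct a runnable model."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateObservation:
    """A cumulative event rate observed over a finite window.

    Parameters
    ----------
    rate
        Proportion of subjects experiencing the event, in ``[0, 1]``.
    window_months
        Length of the observation window in months, strictly positive.
    """

    rate: float
    window_months: float


@dataclass(frozen=True)
class CycleProbability:
    """A per-cycle transition probability with its sensitivity bounds."""

    value: float
    low: float | None = None
    high: float | None = None
    distribution_family: str = "beta"  # {"beta", "fixed"}

    def __post_init__(self) -> None:
        if self.low is None:
            object.__setattr__(self, "low", self.value)
        if self.high is None:
            object.__setattr__(self, "high", self.value)


@dataclass(frozen=True)
class CostParameter:
    """A cost input (USD) with sensitivity bounds and accrual basis."""

    mean: float
    low: float | None = None
    high: float | None = None
    distribution_family: str = "gamma"  # {"gamma", "fixed"}
    basis: str = "per_cycle"  # {"per_cycle", "per_admission"}

    def __post_init__(self) -> None:
        if self.low is None:
            object.__setattr__(self, "low", self.mean)
        if self.high is None:
            object.__setattr__(self, "high", self.mean)


@dataclass(frozen=True)
class UtilityWeight:
    """QALYs accrued per cycle of full occupancy of a health state."""

    per_cycle_weight: float
    low: float | None = None
    high: float | None = None
    distribution_family: str = "beta"  # {"beta", "fixed"}

    def __post_init__(self) -> None:
        if self.low is None:
            object.__setattr__(self, "low", self.per_cycle_weight)
        if self.high is None:
            object.__setattr__(self, "high", self.per_cycle_weight)


@dataclass(frozen=True)
class MortalityBand:
    age_low: float
    age_high: float
    annual_probability: float


@dataclass(frozen=True)
class MortalityTable:
    """Age-banded annual death probabilities; bands ordered and contiguous."""

    bands: tuple[MortalityBand, ...]

    def band_for_age(self, age: float) -> MortalityBand:
        if not self.bands:
            raise ConfigurationError("mortality table is empty")
        if age <= self.bands[0].age_low:
            return self.bands[0]
        chosen = self.bands[0]
        for band in self.bands:
            if band.age_low <= age:
                chosen = band
        return chosen


@dataclass(frozen=True)
class SharedCosts:
    """Costs shared across strategies."""

    hospitalization: CostParameter
    outpatient_stable: CostParameter
    outpatient_nonstable: CostParameter


@dataclass(frozen=True)
class ArmParameters:
    """Per-strategy transition probabilities and per-cycle drug costs.

    ``drug_cost_cycle_nonstable`` exists separately from the stable-state
    cost because, in the 3-monthly injectable arm, acutely unstable patients
    are treated with the 1-monthly product, so that arm carries the
    1-monthly drug cost while the cohort sits in the non-stable state.
    """

    arm_name: str
    p_disc_nonstable: CycleProbability
    p_disc_stable: CycleProbability
    p_relapse_stable: CycleProbability
    p_relapse_nonadherent: CycleProbability
    p_hosp_nonstable: CycleProbability
    drug_cost_cycle_stable: CostParameter
    drug_cost_cycle_nonstable: CostParameter


@dataclass(frozen=True)
class ModelConfig:
    """Strategy-independent model settings and shared parameters."""

    horizon_years: float = 20.0
    cycle_months: float = 3.0
    annual_discount_rate: float = 0.05
    start_age: float = 38.0
    wtp_per_qaly: float = 12_756.55
    utilities: Mapping[str, UtilityWeight] = field(default_factory=dict)
    shared_costs: SharedCosts | None = None
    mortality: MortalityTable | None = None
    relapse_hospitalization_policy: str = "never"  # {"always", "never"}

    @property
    def cycle_years(self) -> float:
        return self.cycle_months / 12.0

    @property
    def n_cycles(self) -> int:
        """Number of whole cycles in the horizon."""
        raw = self.horizon_years * 12.0 / self.cycle_months
        n = round(raw)
        if abs(raw - n) > 1e-9:
            raise ConfigurationError(
                f"horizon of {self.horizon_years} years is not a whole number "
                f"of {self.cycle_months}-month cycles"
            )
        return n

    def with_horizon_cycles(self, n_cycles: int) -> "ModelConfig":
        return replace(self, horizon_years=n_cycles * self.cycle_months / 12.0)


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------


def rate_to_cycle_prob(obs: RateObservation, cycle_months: float) -> float:
    """Convert an event rate over a window to a per-cycle probability.

    Assumes a constant hazard: ``r = -ln(1 - S) / t`` over the observation
    window of ``t`` months, then ``P = 1 - exp(-r * T)`` for a cycle of
    ``T`` months.  The conversion is the identity when ``T == t`` and is
    strictly increasing in both the rate and the cycle length.
    """
    if not 0.0 <= obs.rate <= 1.0:
        raise DomainError(f"rate {obs.rate} outside [0, 1]")
    if obs.window_months <= 0:
        raise DomainError(f"window_months {obs.window_months} must be > 0")
    if cycle_months <= 0:
        raise DomainError(f"cycle_months {cycle_months} must be > 0")
    if obs.rate == 1.0:
        return 1.0
    hazard = -math.log1p(-obs.rate) / obs.window_months
    return -math.expm1(-hazard * cycle_months)


def cycle_prob_to_rate(p: float, cycle_months: float, window_months: float) -> float:
    """Inverse of :func:`rate_to_cycle_prob`: per-cycle probability back to
    the cumulative rate over ``window_months`` under the same constant hazard."""
    return rate_to_cycle_prob(RateObservation(p, cycle_months), window_months)


def annual_prob_to_cycle(q_annual: float, cycle_months: float) -> float:
    """Convert an annual probability to a per-cycle probability.

    Specialization of the constant-hazard conversion with a 12-month window:
    ``1 - (1 - q)^(T/12)``.  ``q_annual == 1`` maps to 1.
    """
    if not 0.0 <= q_annual <= 1.0:
        raise DomainError(f"annual probability {q_annual} outside [0, 1]")
    if cycle_months <= 0:
        raise DomainError(f"cycle_months {cycle_months} must be > 0")
    if q_annual == 1.0:
        return 1.0
    return -math.expm1(math.log1p(-q_annual) * cycle_months / 12.0)


def mortality_for_age(table: MortalityTable, age: float, cycle_months: float) -> float:
    """Per-cycle death probability at a given cohort age.

    Ages outside the table clamp to the nearest edge band.
    """
    if age < 0:
        raise DomainError(f"age {age} must be >= 0")
    band = table.band_for_age(age)
    return annual_prob_to_cycle(band.annual_probability, cycle_months)


def drug_cost_per_cycle(
    price_per_mg: float, dose_mg_per_day: float, days_per_cycle: float
) -> float:
    """Per-cycle drug cost from a unit price and a mean daily dose.

    Used only when constructing scenarios from unit prices; the reference
    parameter set stores the published per-cycle costs verbatim (the
    recomputation differs by <0.2% due to unit-price rounding).
    """
    if price_per_mg < 0 or dose_mg_per_day < 0 or days_per_cycle < 0:
        raise DomainError("all inputs must be >= 0")
    return price_per_mg * dose_mg_per_day * days_per_cycle


# ---------------------------------------------------------------------------
# reference parameter set
# ---------------------------------------------------------------------------

#: 12-month cumulative event rates from the source trials (stable/adherent
#: relapse and discontinuation; non-stable hospitalization).  These are the
#: raw inputs behind the injectable arms' per-cycle probabilities.
SOURCE_EVENT_RATES: dict[str, dict[str, float]] = {
    "relapse_stable": {"PP1M": 0.1119, "PP3M": 0.0924, "ER": 0.3200},
    "disc_stable": {"PP1M": 0.1797, "PP3M": 0.1627, "ER": 0.2188},
    "hosp_nonstable": {"PP1M": 0.0400, "PP3M": 0.0300, "ER": 0.0600},
}

#: 2022 national negotiation prices (USD per mg).
PRICE_PER_MG = {"PP1M": 2.68, "PP3M": 1.96, "ER": 0.89}

#: Mean dose of exposure (mg per day) from the source trials.
MEAN_DAILY_DOSE_MG = {"PP1M": 3.97, "PP3M": 4.61}


def _beta_prob(value: float, low: float, high: float) -> CycleProbability:
    return CycleProbability(value, low, high, "beta")


def _gamma_cost(mean: float, low: float, high: float, basis: str = "per_cycle") -> CostParameter:
    return CostParameter(mean, low, high, "gamma", basis)


_PP1M_DRUG = _gamma_cost(958.87, 767.10, 1150.65)


def load_reference_parameters() -> tuple[dict[str, ArmParameters], ModelConfig]:
    """The embedded reference parameter set for the three-strategy base case.

    Returns an ordered mapping ``{"PP1M": ..., "PP3M": ..., "ER": ...}`` and
    the shared model configuration.  The 3-monthly arm's non-stable state
    carries the 1-monthly drug cost (acute patients receive the 1-monthly
    product or the oral, never the 3-monthly one).
    """
    pp1m = ArmParameters(
        arm_name="PP1M",
        p_disc_nonstable=_beta_prob(0.2140, 0.1926, 0.2354),
        p_disc_stable=_beta_prob(0.0483, 0.0435, 0.0531),
        p_relapse_stable=_beta_prob(0.0292, 0.0263, 0.0321),
        p_relapse_nonadherent=_beta_prob(0.4731, 0.4258, 0.5204),
        p_hosp_nonstable=_beta_prob(0.0102, 0.0091, 0.0112),
        drug_cost_cycle_stable=_PP1M_DRUG,
        drug_cost_cycle_nonstable=_PP1M_DRUG,
    )
    pp3m = ArmParameters(
        arm_name="PP3M",
        p_disc_nonstable=_beta_prob(0.2140, 0.1926, 0.2354),
        p_disc_stable=_beta_prob(0.0434, 0.0391, 0.0477),
        p_relapse_stable=_beta_prob(0.0240, 0.0216, 0.0264),
        p_relapse_nonadherent=_beta_prob(0.3465, 0.3119, 0.3812),
        p_hosp_nonstable=_beta_prob(0.0076, 0.0071, 0.0083),
        drug_cost_cycle_stable=_gamma_cost(813.64, 650.91, 976.36),
        drug_cost_cycle_nonstable=_PP1M_DRUG,
    )
    er = ArmParameters(
        arm_name="ER",
        p_disc_nonstable=_beta_prob(0.2831, 0.2548, 0.3114),
        p_disc_stable=_beta_prob(0.1792, 0.1613, 0.1971),
        p_relapse_stable=_beta_prob(0.2655, 0.2390, 0.2921),
        p_relapse_nonadherent=_beta_prob(0.9864, 0.8878, 1.0),
        p_hosp_nonstable=_beta_prob(0.0503, 0.0453, 0.0554),
        drug_cost_cycle_stable=_gamma_cost(759.09, 607.27, 910.91),
        drug_cost_cycle_nonstable=_gamma_cost(759.09, 607.27, 910.91),
    )
    config = ModelConfig(
        horizon_years=20.0,
        cycle_months=3.0,
        annual_discount_rate=0.05,
        start_age=38.0,
        wtp_per_qaly=12_756.55,
        utilities={
            "stable": UtilityWeight(0.23, 0.21, 0.25, "beta"),
            "non_stable": UtilityWeight(0.15, 0.14, 0.17, "beta"),
        },
        shared_costs=SharedCosts(
            hospitalization=_gamma_cost(1998.90, 1599.12, 2398.68, basis="per_admission"),
            outpatient_stable=_gamma_cost(127.52, 102.02, 153.03),
            outpatient_nonstable=_gamma_cost(183.30, 164.97, 219.96),
        ),
        mortality=MortalityTable(
            bands=(
                MortalityBand(35, 39, 0.006267),
                MortalityBand(40, 44, 0.004904),
                MortalityBand(45, 49, 0.007708),
                MortalityBand(50, 54, 0.007606),
                MortalityBand(55, 59, 0.011745),
                MortalityBand(60, 64, 0.035610),
                MortalityBand(65, 78, 0.016676),
            )
        ),
        relapse_hospitalization_policy="never",
    )
    return {"PP1M": pp1m, "PP3M": pp3m, "ER": er}, config


def reference_parameters_frame():
    """The reference parameter set flattened to a table (one row per input)."""
    import pandas as pd

    arms, config = load_reference_parameters()
    rows: list[dict] = []

    def prob_row(block: str, arm: str, p: CycleProbability) -> dict:
        return dict(
            block=block, arm=arm, value=p.value, low=p.low, high=p.high,
            distribution=p.distribution_family, basis="per_cycle",
        )

    prob_fields = [
        ("all_cause_discontinuation_nonstable", "p_disc_nonstable"),
        ("all_cause_discontinuation_stable_adherent", "p_disc_stable"),
        ("relapse_stable_adherent", "p_relapse_stable"),
        ("relapse_stable_nonadherent", "p_relapse_nonadherent"),
        ("hospitalization_nonstable", "p_hosp_nonstable"),
    ]
    for block, field_name in prob_fields:
        for arm_name, arm in arms.items():
            rows.append(prob_row(block, arm_name, getattr(arm, field_name)))
    for arm_name, arm in arms.items():
        c = arm.drug_cost_cycle_stable
        rows.append(dict(block="drug_cost", arm=arm_name, value=c.mean, low=c.low,
                         high=c.high, distribution=c.distribution_family, basis=c.basis))
    sc = config.shared_costs
    for name, c in [("hospitalization", sc.hospitalization),
                    ("outpatient_stable", sc.outpatient_stable),
                    ("outpatient_nonstable", sc.outpatient_nonstable)]:
        rows.append(dict(block=name, arm="shared", value=c.mean, low=c.low,
                         high=c.high, distribution=c.distribution_family, basis=c.basis))
    for state, u in config.utilities.items():
        rows.append(dict(block=f"utility_{state}", arm="shared", value=u.per_cycle_weight,
                         low=u.low, high=u.high, distribution=u.distribution_family,
                         basis="per_cycle"))
    for band in config.mortality.bands:
        rows.append(dict(block=f"mortality_{band.age_low:.0f}_{band.age_high:.0f}",
                         arm="shared", value=band.annual_probability,
                         low=band.annual_probability, high=band.annual_probability,
                         distribution="fixed", basis="per_year"))
    rows.append(dict(block="discount_rate", arm="shared",
                     value=config.annual_discount_rate, low=0.0, high=0.08,
                     distribution="fixed", basis="per_year"))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _check_bounds(name: str, low: float, mid: float, high: float,
                  upper: float | None, out: list[str]) -> None:
    if not (low <= mid <= high):
        out.append(f"{name}: bounds not ordered (low={low}, value={mid}, high={high})")
    if low < 0:
        out.append(f"{name}: negative lower bound {low}")
    if upper is not None and high > upper:
        out.append(f"{name}: upper bound {high} exceeds {upper}")


def validate(arms: Iterable[ArmParameters], config: ModelConfig) -> list[str]:
    """Check every invariant; return one human-readable entry per violation.

    Violations are returned, never raised, so callers can report all of them
    at once (and synthetic generators can use this as a rejection predicate).
    """
    violations: list[str] = []
    if isinstance(arms, Mapping):
        arms = arms.values()

    for arm in arms:
        prefix = arm.arm_name
        for field_name in ("p_disc_nonstable", "p_disc_stable", "p_relapse_stable",
                           "p_relapse_nonadherent", "p_hosp_nonstable"):
            p: CycleProbability = getattr(arm, field_name)
            _check_bounds(f"{prefix}.{field_name}", p.low, p.value, p.high, 1.0, violations)
            if p.distribution_family not in ("beta", "fixed"):
                violations.append(f"{prefix}.{field_name}: unknown distribution "
                                  f"family {p.distribution_family!r}")
        for field_name in ("drug_cost_cycle_stable", "drug_cost_cycle_nonstable"):
            c: CostParameter = getattr(arm, field_name)
            _check_bounds(f"{prefix}.{field_name}", c.low, c.mean, c.high, None, violations)
            if c.distribution_family not in ("gamma", "fixed"):
                violations.append(f"{prefix}.{field_name}: unknown distribution "
                                  f"family {c.distribution_family!r}")
        mass = arm.p_disc_stable.value + arm.p_relapse_stable.value
        if mass > 1.0 + 1e-12:
            violations.append(
                f"{prefix}: conditional transition mass out of stable/adherent "
                f"exceeds 1 ({arm.p_disc_stable.value} + {arm.p_relapse_stable.value} "
                f"= {mass})"
            )

    if config.horizon_years < 0:
        violations.append(f"horizon_years must be >= 0, got {config.horizon_years}")
    if config.cycle_months <= 0:
        violations.append(f"cycle_months must be > 0, got {config.cycle_months}")
    else:
        raw = config.horizon_years * 12.0 / config.cycle_months
        if abs(raw - round(raw)) > 1e-9:
            violations.append(
                f"horizon of {config.horizon_years} years is not a whole number of "
                f"{config.cycle_months}-month cycles"
            )
    if not 0.0 <= config.annual_discount_rate <= 1.0:
        violations.append(
            f"annual_discount_rate must be in [0, 1], got {config.annual_discount_rate}")
    if config.relapse_hospitalization_policy not in ("always", "never"):
        violations.append(
            "relapse_hospitalization_policy must be 'always' or 'never', got "
            f"{config.relapse_hospitalization_policy!r}")

    for state in ("stable", "non_stable"):
        if state not in config.utilities:
            violations.append(f"missing utility for state group {state!r}")
            continue
        u = config.utilities[state]
        _check_bounds(f"utility.{state}", u.low, u.per_cycle_weight, u.high, 1.0, violations)

    if config.shared_costs is None:
        violations.append("shared_costs missing")
    else:
        sc = config.shared_costs
        for name, c in [("hospitalization", sc.hospitalization),
                        ("outpatient_stable", sc.outpatient_stable),
                        ("outpatient_nonstable", sc.outpatient_nonstable)]:
            _check_bounds(f"shared_costs.{name}", c.low, c.mean, c.high, None, violations)

    if config.mortality is None or not config.mortality.bands:
        violations.append("mortality table missing or empty")
    else:
        bands = config.mortality.bands
        for band in bands:
            if not 0.0 <= band.annual_probability <= 1.0:
                violations.append(
                    f"mortality band {band.age_low}-{band.age_high}: annual "
                    f"probability {band.annual_probability} outside [0, 1]")
            if band.age_high < band.age_low:
                violations.append(
                    f"mortality band {band.age_low}-{band.age_high}: reversed ages")
        for prev, nxt in zip(bands, bands[1:]):
            if nxt.age_low <= prev.age_low:
                violations.append("mortality bands not ordered by age")
            if nxt.age_low > prev.age_high + 1 + 1e-9:
                violations.append(
                    f"mortality bands leave a gap between {prev.age_high} and "
                    f"{nxt.age_low}")

    return violations
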