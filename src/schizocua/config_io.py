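"""Strict YAML configuration round-tripping.

Schema mirrors the domain types field-for-field.  Unknown keys are errors:
a decision model silently ignoring a misspelt key would be worse than a
crash.  Missing optional keys take the documented defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .parameters import (
    ArmParameters,
    CostParameter,
    CycleProbability,
    ModelConfig,
    MortalityBand,
    MortalityTable,
    SharedCosts,
    UtilityWeight,
    validate,
)

__all__ = ["parse_config", "parse_config_data", "dump_config", "config_to_data",
           "ConfigSchemaError"]


class ConfigSchemaError(ValueError):
    """A configuration file violates the schema; message names the key path."""


def _require_mapping(data: Any, path: str) -> Mapping:
    if not isinstance(data, Mapping):
        raise ConfigSchemaError(f"{path}: expected a mapping, got {type(data).__name__}")
    return data


def _take(data: dict, key: str, path: str, default=..., required: bool = False):
    if key in data:
        return data.pop(key)
    if required or default is ...:
        raise ConfigSchemaError(f"{path}: missing required key {key!r}")
    return default


def _no_leftovers(data: dict, path: str) -> None:
    if data:
        key = sorted(data)[0]
        raise ConfigSchemaError(f"{path}: unknown key {key!r}")


def _prob_from(data: Any, path: str) -> CycleProbability:
    d = dict(_require_mapping(data, path))
    p = CycleProbability(
        value=float(_take(d, "value", path, required=True)),
        low=(None if "low" not in d else float(d.pop("low"))),
        high=(None if "high" not in d else float(d.pop("high"))),
        distribution_family=str(_take(d, "distribution_family", path, "beta")),
    )
    _no_leftovers(d, path)
    return p


def _cost_from(data: Any, path: str, basis: str = "per_cycle") -> CostParameter:
    d = dict(_require_mapping(data, path))
    c = CostParameter(
        mean=float(_take(d, "mean", path, required=True)),
        low=(None if "low" not in d else float(d.pop("low"))),
        high=(None if "high" not in d else float(d.pop("high"))),
        distribution_family=str(_take(d, "distribution_family", path, "gamma")),
        basis=str(_take(d, "basis", path, basis)),
    )
    _no_leftovers(d, path)
    return c


def _utility_from(data: Any, path: str) -> UtilityWeight:
    d = dict(_require_mapping(data, path))
    u = UtilityWeight(
        per_cycle_weight=float(_take(d, "per_cycle_weight", path, required=True)),
        low=(None if "low" not in d else float(d.pop("low"))),
        high=(None if "high" not in d else float(d.pop("high"))),
        distribution_family=str(_take(d, "distribution_family", path, "beta")),
    )
    _no_leftovers(d, path)
    return u


def _arm_from(data: Any, path: str) -> ArmParameters:
    d = dict(_require_mapping(data, path))
    arm = ArmParameters(
        arm_name=str(_take(d, "arm_name", path, required=True)),
        p_disc_nonstable=_prob_from(_take(d, "p_disc_nonstable", path, required=True),
                                    f"{path}.p_disc_nonstable"),
        p_disc_stable=_prob_from(_take(d, "p_disc_stable", path, required=True),
                                 f"{path}.p_disc_stable"),
        p_relapse_stable=_prob_from(_take(d, "p_relapse_stable", path, required=True),
                                    f"{path}.p_relapse_stable"),
        p_relapse_nonadherent=_prob_from(
            _take(d, "p_relapse_nonadherent", path, required=True),
            f"{path}.p_relapse_nonadherent"),
        p_hosp_nonstable=_prob_from(_take(d, "p_hosp_nonstable", path, required=True),
                                    f"{path}.p_hosp_nonstable"),
        drug_cost_cycle_stable=_cost_from(
            _take(d, "drug_cost_cycle_stable", path, required=True),
            f"{path}.drug_cost_cycle_stable"),
        drug_cost_cycle_nonstable=_cost_from(
            _take(d, "drug_cost_cycle_nonstable", path, required=True),
            f"{path}.drug_cost_cycle_nonstable"),
    )
    _no_leftovers(d, path)
    return arm


def parse_config_data(data: Any) -> tuple[dict[str, ArmParameters], ModelConfig]:
    """Build and validate a parameter set from already-parsed YAML data."""
    d = dict(_require_mapping(data, "$"))
    cfg_data = dict(_require_mapping(_take(d, "config", "$", required=True), "config"))
    arms_data = _take(d, "arms", "$", required=True)
    _no_leftovers(d, "$")

    utilities_data = dict(_require_mapping(
        _take(cfg_data, "utilities", "config", required=True), "config.utilities"))
    utilities = {state: _utility_from(utilities_data.pop(state),
                                      f"config.utilities.{state}")
                 for state in list(utilities_data)}

    sc_data = dict(_require_mapping(
        _take(cfg_data, "shared_costs", "config", required=True), "config.shared_costs"))
    shared_costs = SharedCosts(
        hospitalization=_cost_from(
            _take(sc_data, "hospitalization", "config.shared_costs", required=True),
            "config.shared_costs.hospitalization", basis="per_admission"),
        outpatient_stable=_cost_from(
            _take(sc_data, "outpatient_stable", "config.shared_costs", required=True),
            "config.shared_costs.outpatient_stable"),
        outpatient_nonstable=_cost_from(
            _take(sc_data, "outpatient_nonstable", "config.shared_costs", required=True),
            "config.shared_costs.outpatient_nonstable"),
    )
    _no_leftovers(sc_data, "config.shared_costs")

    mort_data = dict(_require_mapping(
        _take(cfg_data, "mortality", "config", required=True), "config.mortality"))
    bands_raw = _take(mort_data, "bands", "config.mortality", required=True)
    _no_leftovers(mort_data, "config.mortality")
    if not isinstance(bands_raw, list):
        raise ConfigSchemaError("config.mortality.bands: expected a list")
    bands = []
    for i, row in enumerate(bands_raw):
        if not isinstance(row, (list, tuple)) or len(row) != 3:
            raise ConfigSchemaError(
                f"config.mortality.bands[{i}]: expected [age_low, age_high, "
                "annual_probability]")
        bands.append(MortalityBand(float(row[0]), float(row[1]), float(row[2])))

    config = ModelConfig(
        horizon_years=float(_take(cfg_data, "horizon_years", "config", 20.0)),
        cycle_months=float(_take(cfg_data, "cycle_months", "config", 3.0)),
        annual_discount_rate=float(_take(cfg_data, "annual_discount_rate", "config", 0.05)),
        start_age=float(_take(cfg_data, "start_age", "config", 38.0)),
        wtp_per_qaly=float(_take(cfg_data, "wtp_per_qaly", "config", 12_756.55)),
        utilities=utilities,
        shared_costs=shared_costs,
        mortality=MortalityTable(bands=tuple(bands)),
        relapse_hospitalization_policy=str(
            _take(cfg_data, "relapse_hospitalization_policy", "config", "never")),
    )
    _no_leftovers(cfg_data, "config")

    if not isinstance(arms_data, list):
        raise ConfigSchemaError("arms: expected a list of arm mappings")
    arms: dict[str, ArmParameters] = {}
    for i, arm_data in enumerate(arms_data):
        arm = _arm_from(arm_data, f"arms[{i}]")
        arms[arm.arm_name] = arm

    violations = validate(arms, config)
    if violations:
        raise ConfigSchemaError("validation failed: " + "; ".join(violations))
    return arms, config


def parse_config(path: str | Path) -> tuple[dict[str, ArmParameters], ModelConfig]:
    """Load and validate a parameter set from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return parse_config_data(data)


def _prob_data(p: CycleProbability) -> dict:
    return {"value": p.value, "low": p.low, "high": p.high,
            "distribution_family": p.distribution_family}


def _cost_data(c: CostParameter) -> dict:
    return {"mean": c.mean, "low": c.low, "high": c.high,
            "distribution_family": c.distribution_family, "basis": c.basis}


def config_to_data(arms: Mapping[str, ArmParameters], config: ModelConfig) -> dict:
    """Serialize a parameter set to plain data (the inverse of
    :func:`parse_config_data`)."""
    return {
        "config": {
            "horizon_years": config.horizon_years,
            "cycle_months": config.cycle_months,
            "annual_discount_rate": config.annual_discount_rate,
            "start_age": config.start_age,
            "wtp_per_qaly": config.wtp_per_qaly,
            "utilities": {
                state: {"per_cycle_weight": u.per_cycle_weight, "low": u.low,
                        "high": u.high, "distribution_family": u.distribution_family}
                for state, u in config.utilities.items()
            },
            "shared_costs": {
                "hospitalization": _cost_data(config.shared_costs.hospitalization),
                "outpatient_stable": _cost_data(config.shared_costs.outpatient_stable),
                "outpatient_nonstable": _cost_data(config.shared_costs.outpatient_nonstable),
            },
            "mortality": {
                "bands": [[b.age_low, b.age_high, b.annual_probability]
                          for b in config.mortality.bands]
            },
            "relapse_hospitalization_policy": config.relapse_hospitalization_policy,
        },
        "arms": [
            {
                "arm_name": arm.arm_name,
                "p_disc_nonstable": _prob_data(arm.p_disc_nonstable),
                "p_disc_stable": _prob_data(arm.p_disc_stable),
                "p_relapse_stable": _prob_data(arm.p_relapse_stable),
                "p_relapse_nonadherent": _prob_data(arm.p_relapse_nonadherent),
                "p_hosp_nonstable": _prob_data(arm.p_hosp_nonstable),
                "drug_cost_cycle_stable": _cost_data(arm.drug_cost_cycle_stable),
                "drug_cost_cycle_nonstable": _cost_data(arm.drug_cost_cycle_nonstable),
            }
            for arm in arms.values()
        ],
    }


def dump_config(arms: Mapping[str, ArmParameters], config: ModelConfig,
                path: str | Path) -> None:
    """Write a parameter set to YAML; round-trips losslessly."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_data(arms, config), fh, sort_keys=False)
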