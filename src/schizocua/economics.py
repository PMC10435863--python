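"""Pairwise incremental analysis: ICERs, dominance, NMB, WTP decision rules."""

from __future__ import annotations

from dataclasses import dataclass

from .markov import StrategyResult
from .parameters import DomainError

__all__ = [
    "ComparisonResult",
    "WtpDecision",
    "compare",
    "net_monetary_benefit",
    "wtp_verdict",
    "NotClassifiableError",
]

ICER_DEFINED = "icer_defined"
INTERVENTION_DOMINANT = "intervention_dominant"
COMPARATOR_DOMINANT = "comparator_dominant"
EQUAL_EFFECTS = "equal_effects"


class NotClassifiableError(ValueError):
    """A WTP verdict was requested for a comparison with no ICER and no
    dominance direction (equal costs and effects)."""


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental outcome of one strategy against a comparator.

    ``icer`` is ``None`` unless ``classification == "icer_defined"``, in
    which case it equals ``delta_cost / delta_qaly`` (kept at full
    precision; rounding is a reporting concern).
    """

    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    classification: str


@dataclass(frozen=True)
class WtpDecision:
    icer: float | None
    gdp_per_capita: float
    verdict: str  # {"very_cost_effective", "cost_effective", "not_cost_effective", "dominant"}


def compare(intervention: StrategyResult, comparator: StrategyResult) -> ComparisonResult:
    """Incremental cost, incremental QALYs and (when defined) the ICER.

    Dominance: strictly cheaper and strictly more effective means the
    intervention dominates (and symmetrically for the comparator).  Equal
    effects with unequal cost are classified by the cost sign without an
    ICER; identical cost and effects yield ``equal_effects``.
    """
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.total_qaly - comparator.total_qaly

    if dq == 0.0:
        if dc == 0.0:
            cls = EQUAL_EFFECTS
        elif dc < 0.0:
            cls = INTERVENTION_DOMINANT
        else:
            cls = COMPARATOR_DOMINANT
        icer = None
    elif dq > 0.0 and dc < 0.0:
        cls, icer = INTERVENTION_DOMINANT, None
    elif dq < 0.0 and dc > 0.0:
        cls, icer = COMPARATOR_DOMINANT, None
    else:
        cls, icer = ICER_DEFINED, dc / dq

    return ComparisonResult(
        intervention=intervention.arm_name,
        comparator=comparator.arm_name,
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer,
        classification=cls,
    )


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """``wtp * total_qaly - total_cost`` (USD); linear in the threshold."""
    if wtp < 0:
        raise DomainError(f"wtp must be >= 0, got {wtp}")
    return wtp * result.total_qaly - result.total_cost


def wtp_verdict(comparison: ComparisonResult, gdp: float) -> WtpDecision:
    """GDP-multiple decision rule.

    Strictly below 1x GDP per QALY: very cost-effective.  Between 1x
    (inclusive) and 3x (exclusive): cost-effective.  At or above 3x: not
    cost-effective.  A dominant intervention is ``dominant`` at any GDP; a
    dominated one is ``not_cost_effective``.
    """
    if gdp <= 0:
        raise DomainError(f"gdp must be > 0, got {gdp}")
    if comparison.classification == INTERVENTION_DOMINANT:
        return WtpDecision(None, gdp, "dominant")
    if comparison.classification == COMPARATOR_DOMINANT:
        return WtpDecision(None, gdp, "not_cost_effective")
    if comparison.icer is None:
        raise NotClassifiableError(
            f"{comparison.intervention} vs {comparison.comparator}: no ICER "
            "and no dominance direction"
        )
    icer = comparison.icer
    if icer < gdp:
        verdict = "very_cost_effective"
    elif icer < 3.0 * gdp:
        verdict = "cost_effective"
    else:
        verdict = "not_cost_effective"
    return WtpDecision(icer, gdp, verdict)
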