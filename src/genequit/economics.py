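"""Incremental cost-effectiveness: ICER, net monetary benefit, dominance,
and the short-term (12-month) cost-per-quitter analysis.

Conventions: the comparator (usual smoking cessation, USC) is subtracted
from the intervention (genetic-test arm, GT), so delta_cost = C_GT - C_USC
and delta_effect = E_GT - E_USC.  ICER = delta_cost / delta_effect when both
deltas are positive; an intervention that is cheaper and more effective is
"dominant", one that is costlier and less effective is "dominated"; a zero
effect difference leaves the ratio undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .markov import CohortTrace, run_cohort
from .parameters import ModelConfig, StrategyDefinition, intervention_cost

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


def icer(delta_cost: float, delta_effect: float) -> float | str:
    """ICER or a dominance label.

    Returns the ratio for a conventional trade-off (both deltas positive)
    and for the rarely seen south-west quadrant (both negative, where the
    ratio reads as savings per unit of effect forgone); otherwise one of the
    labels ``dominant`` / ``dominated`` / ``undefined``.
    """
    if delta_effect == 0.0:
        return UNDEFINED
    if delta_effect > 0.0 and delta_cost <= 0.0:
        return DOMINANT
    if delta_effect < 0.0 and delta_cost >= 0.0:
        return DOMINATED
    return delta_cost / delta_effect


def nmb(wtp: float, cost: float, effect: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp``: wtp*effect - cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * effect - cost


def round_dollars(x: float) -> int:
    """Round to whole dollars, half-up (reporting convention)."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class CEResult:
    label: str
    cost_usc: float
    cost_gt: float
    qaly_usc: float
    qaly_gt: float
    wtp: float

    @property
    def delta_cost(self) -> float:
        return self.cost_gt - self.cost_usc

    @property
    def delta_effect(self) -> float:
        return self.qaly_gt - self.qaly_usc

    @property
    def icer(self) -> float | str:
        return icer(self.delta_cost, self.delta_effect)

    @property
    def incremental_nmb(self) -> float:
        return nmb(self.wtp, self.delta_cost, self.delta_effect)

    @property
    def dominance(self) -> str:
        v = self.icer
        if v == DOMINANT:
            return DOMINANT
        if v == DOMINATED:
            return DOMINATED
        return "tradeoff"

    def as_dict(self) -> dict:
        v = self.icer
        return {
            "label": self.label,
            "cost_usc": self.cost_usc, "cost_gt": self.cost_gt,
            "qaly_usc": self.qaly_usc, "qaly_gt": self.qaly_gt,
            "delta_cost": self.delta_cost, "delta_effect": self.delta_effect,
            "icer": v if isinstance(v, str) else round_dollars(v),
            "icer_raw": v if not isinstance(v, str) else None,
            "incremental_nmb": self.incremental_nmb,
            "dominance": self.dominance, "wtp": self.wtp,
        }


def evaluate(config: ModelConfig, label: str = "base case"
             ) -> tuple[CEResult, CohortTrace, CohortTrace]:
    """Run both arms of the model and combine them into a CEResult."""
    usc = run_cohort(config.usc, config)
    gt = run_cohort(config.gt, config)
    result = CEResult(label=label,
                      cost_usc=usc.total_cost, cost_gt=gt.total_cost,
                      qaly_usc=usc.total_qaly, qaly_gt=gt.total_qaly,
                      wtp=config.wtp)
    return result, usc, gt


@dataclass
class ShortTermResult:
    """The 12-month view: intervention cost per additional quitter."""
    cohort_size: int
    cost_usc: Decimal
    cost_gt: Decimal
    quitters_usc: int
    quitters_gt: int

    @property
    def delta_cost(self) -> Decimal:
        return self.cost_gt - self.cost_usc

    @property
    def delta_quitters(self) -> int:
        return self.quitters_gt - self.quitters_usc

    @property
    def cost_per_additional_quitter(self) -> float | str:
        if self.delta_quitters == 0:
            return UNDEFINED
        return float(self.delta_cost) / self.delta_quitters

    def as_dict(self) -> dict:
        cpq = self.cost_per_additional_quitter
        return {"cohort_size": self.cohort_size,
                "cost_usc": float(self.cost_usc), "cost_gt": float(self.cost_gt),
                "quitters_usc": self.quitters_usc, "quitters_gt": self.quitters_gt,
                "delta_cost": float(self.delta_cost),
                "delta_quitters": self.delta_quitters,
                "cost_per_additional_quitter":
                    cpq if isinstance(cpq, str) else round_dollars(cpq)}


def short_term(cohort: int, usc: StrategyDefinition, gt: StrategyDefinition
               ) -> ShortTermResult:
    """Cost per additional quitter at 12 months for ``cohort`` persons per arm."""
    if cohort <= 0:
        raise ValueError("cohort size must be positive")
    return ShortTermResult(
        cohort_size=cohort,
        cost_usc=cohort * intervention_cost(usc),
        cost_gt=cohort * intervention_cost(gt),
        quitters_usc=round(cohort * usc.quit_rate_12m),
        quitters_gt=round(cohort * gt.quit_rate_12m),
    )
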