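"""Incremental cost-effectiveness analysis: ICERs, willingness-to-pay
comparison, price-threshold solving and payer-share scenarios.

The comparison is pairwise (intervention vs comparator).  ICERs are always
computed from full-precision increments; rounding happens only when
results are written out.  When the incremental QALY is non-positive the
ratio is replaced by a dominance flag.  Net monetary benefit
(WTP * dQALY - dCost) is carried as the decision statistic used by the
probabilistic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping

from .config import ModelConfig
from .costing import CostAccumulator, accumulate_costs
from .markov import OutcomeAccumulator, accumulate_outcomes, build_trace

__all__ = [
    "ArmResult",
    "CEAResult",
    "evaluate_arm",
    "evaluate_model",
    "compute_icer",
    "net_monetary_benefit",
    "price_threshold",
    "payer_share_scenario",
]


@dataclass(frozen=True)
class ArmResult:
    label: str
    cost: float
    ly: float
    qaly: float


@dataclass(frozen=True)
class CEAResult:
    """Pairwise comparison of an intervention against a comparator arm."""

    reference: ArmResult
    comparison: ArmResult
    wtp_per_qaly: float

    @property
    def incr_cost(self) -> float:
        return self.comparison.cost - self.reference.cost

    @property
    def incr_ly(self) -> float:
        return self.comparison.ly - self.reference.ly

    @property
    def incr_qaly(self) -> float:
        return self.comparison.qaly - self.reference.qaly

    @property
    def dominance(self) -> str | None:
        """'dominant' (cheaper, more effective), 'dominated' (dearer, less
        effective), 'equal-effect', or None when the ICER is well-defined."""
        if self.incr_qaly > 0:
            return "dominant" if self.incr_cost < 0 else None
        if self.incr_qaly == 0:
            return "equal-effect"
        return "dominated" if self.incr_cost >= 0 else None

    @property
    def icer_qaly(self) -> float | None:
        if self.incr_qaly <= 0:
            return None
        return self.incr_cost / self.incr_qaly

    @property
    def icer_ly(self) -> float | None:
        if self.incr_ly <= 0:
            return None
        return self.incr_cost / self.incr_ly

    @property
    def nmb(self) -> float:
        return self.wtp_per_qaly * self.incr_qaly - self.incr_cost

    @property
    def cost_effective_at_wtp(self) -> bool:
        if self.incr_qaly > 0:
            return self.incr_cost <= self.wtp_per_qaly * self.incr_qaly
        return self.incr_cost < 0  # no health gain: only saving money qualifies

    def to_dict(self) -> dict:
        return {
            "arms": {
                a.label: {"cost": a.cost, "ly": a.ly, "qaly": a.qaly}
                for a in (self.reference, self.comparison)
            },
            "reference": self.reference.label,
            "comparison": self.comparison.label,
            "wtp_per_qaly": self.wtp_per_qaly,
            "incr_cost": self.incr_cost,
            "incr_ly": self.incr_ly,
            "incr_qaly": self.incr_qaly,
            "icer_qaly": self.icer_qaly,
            "icer_ly": self.icer_ly,
            "dominance": self.dominance,
            "nmb": self.nmb,
            "cost_effective_at_wtp": self.cost_effective_at_wtp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CEAResult":
        arms = {
            label: ArmResult(label=label, **vals) for label, vals in d["arms"].items()
        }
        return cls(
            reference=arms[d["reference"]],
            comparison=arms[d["comparison"]],
            wtp_per_qaly=d["wtp_per_qaly"],
        )


def compute_icer(
    ref: ArmResult, comp: ArmResult, wtp_per_qaly: float
) -> CEAResult:
    """Pair two evaluated arms into an incremental result."""
    return CEAResult(reference=ref, comparison=comp, wtp_per_qaly=wtp_per_qaly)


def net_monetary_benefit(result: CEAResult, wtp: float) -> float:
    return wtp * result.incr_qaly - result.incr_cost


def evaluate_arm(
    config: ModelConfig,
    arm_label: str,
    values: Mapping[str, float] | None = None,
) -> ArmResult:
    """Run the cohort model for one arm: trace, outcomes and costs."""
    arm = config.arms[arm_label]
    pair = config.survival[arm_label]
    rate = None
    if values is not None and "settings.annual_discount_rate" in values:
        rate = float(values["settings.annual_discount_rate"])
    trace = build_trace(pair.pfs, pair.os, config.settings, discount_rate=rate)
    out = accumulate_outcomes(trace, config.utilities, arm, config.settings, values)
    cost = accumulate_costs(trace, arm, config.costs, config.settings, values)
    return ArmResult(
        label=arm_label, cost=cost.total_disc, ly=out.ly_disc, qaly=out.qaly_disc
    )


def evaluate_model(
    config: ModelConfig,
    overrides: Mapping[str, float] | None = None,
    comparison: str = "pembrolizumab",
    reference: str = "chemotherapy",
) -> CEAResult:
    """Full pairwise evaluation of a configuration.

    ``overrides`` maps flat parameter names (see
    :meth:`ModelConfig.flat_params`) to values replacing the base case;
    unknown names raise KeyError.
    """
    values = config.flat_params()
    if overrides:
        unknown = set(overrides) - set(values)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        values.update(overrides)
    return compute_icer(
        ref=evaluate_arm(config, reference, values),
        comp=evaluate_arm(config, comparison, values),
        wtp_per_qaly=config.settings.wtp_per_qaly,
    )


def payer_share_scenario(result: CEAResult, patient_share: float) -> CEAResult:
    """Scale the incremental cost by the patient's share of drug spending.

    With an 80/20 insurer/patient split the patient faces 20% of the
    incremental cost, scaling the ICER by 0.2; health outcomes are
    unchanged.  Implemented by shifting the comparison arm's cost so that
    incr_cost' = patient_share * incr_cost.
    """
    if not (0.0 <= patient_share <= 1.0):
        raise ValueError(f"patient_share must be in [0, 1], got {patient_share}")
    new_cost = result.reference.cost + patient_share * result.incr_cost
    return replace(result, comparison=replace(result.comparison, cost=new_cost))


def price_threshold(
    config: ModelConfig,
    target_wtp: float,
    price_param: str = "cost.drug.pembrolizumab",
    tol: float = 0.01,
    model: Callable[[float], CEAResult] | None = None,
) -> dict:
    """Per-cycle price at which the ICER equals ``target_wtp``.

    The incremental cost is affine in any unit price, so the crossing is
    found by bisection on [0, base price] to +/-``tol`` dollars; tests
    cross-check the result against the closed-form solve implied by that
    linearity.  ``model`` may replace the default closure (price ->
    CEAResult) for scenario variants.

    Returns a dict with the threshold price, the implied reduction
    fraction vs the base price, and the achieved ICER; if the ICER never
    crosses the target on [0, base] a boundary report is returned with
    ``crossed = False``.
    """
    base_price = config.flat_params()[price_param]
    if model is None:
        def model(price: float) -> CEAResult:
            return evaluate_model(config, {price_param: price})

    def icer(price: float) -> float:
        res = model(price)
        if res.incr_qaly <= 0:
            raise ValueError("price threshold undefined: no QALY gain")
        return res.incr_cost / res.incr_qaly

    lo, hi = 0.0, float(base_price)
    f_lo, f_hi = icer(lo), icer(hi)
    if not (min(f_lo, f_hi) <= target_wtp <= max(f_lo, f_hi)):
        return {
            "crossed": False,
            "price": lo if abs(f_lo - target_wtp) < abs(f_hi - target_wtp) else hi,
            "base_price": base_price,
            "icer_at_zero": f_lo,
            "icer_at_base": f_hi,
        }
    increasing = f_hi >= f_lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if (icer(mid) < target_wtp) == increasing:
            lo = mid
        else:
            hi = mid
    price = 0.5 * (lo + hi)
    return {
        "crossed": True,
        "price": price,
        "base_price": base_price,
        "reduction": 1.0 - price / base_price if base_price > 0 else 0.0,
        "icer_at_threshold": icer(price),
    }
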