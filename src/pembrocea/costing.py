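"""Discounted cost accumulation per treatment arm.

Four components make up direct medical cost:

* trial drugs, charged per cycle in proportion to progression-free
  occupancy, each drug subject to an optional cycle cap (cisplatin is
  protocol-limited to 8 cycles);
* routine imaging while progression-free, at a fixed per-cycle charge;
* grade >=3 adverse events, a one-time expected cost
  (sum of probability x unit cost) incurred in the first cycle;
* post-progression treatment, a mix-weighted per-cycle regimen cost
  charged for the whole progressed-disease occupancy.

All streams are discounted with the trace's cost discount factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .config import ArmProfile, CostTable, EconSettings
from .markov import CohortTrace

__all__ = [
    "CostAccumulator",
    "expected_ae_cost",
    "followup_cost_per_cycle",
    "accumulate_costs",
]


@dataclass(frozen=True)
class CostAccumulator:
    """Discounted cost components (USD); total is their sum."""

    drug_cost: float
    imaging_cost: float
    ae_cost: float
    followup_cost: float

    @property
    def total_disc(self) -> float:
        return self.drug_cost + self.imaging_cost + self.ae_cost + self.followup_cost


def _val(values: Mapping[str, float] | None, key: str, default: float) -> float:
    return float(values[key]) if values is not None and key in values else default


def expected_ae_cost(
    arm: ArmProfile,
    costs: CostTable,
    values: Mapping[str, float] | None = None,
) -> float:
    """One-time expected adverse-event cost: sum of p_AE * cost_AE."""
    total = 0.0
    for ae, p in arm.ae_probabilities.items():
        if ae not in costs.ae_costs:
            raise KeyError(f"no cost entry for adverse event {ae!r}")
        prob = _val(values, f"ae_prob.{arm.arm_label}.{ae}", p.base)
        cost = _val(values, f"cost.ae.{ae}", costs.ae_costs[ae].base)
        total += prob * cost
    return total


def followup_cost_per_cycle(
    arm: ArmProfile,
    costs: CostTable,
    values: Mapping[str, float] | None = None,
) -> float:
    """Mix-weighted per-cycle cost of post-progression treatment.

    Regimen costs are sums of their member drugs' per-cycle costs; the mix
    weights are normalized to sum to one (identity at base values, where
    the published mixes already sum to 1.00).
    """
    weights = {}
    for cat, w in arm.followup_mix.items():
        if cat not in costs.followup_regimens:
            raise KeyError(f"unknown follow-up category {cat!r}")
        weights[cat] = _val(values, f"followup_mix.{arm.arm_label}.{cat}", w.base)
    total_w = sum(weights.values())
    if total_w <= 0:
        raise ValueError("follow-up mix weights sum to zero")
    cost = 0.0
    for cat, w in weights.items():
        regimen = sum(
            _val(values, f"cost.drug.{d}", costs.per_cycle_drug_costs[d].base)
            for d in costs.followup_regimens[cat]
        )
        cost += (w / total_w) * regimen
    return cost


def accumulate_costs(
    trace: CohortTrace,
    arm: ArmProfile,
    costs: CostTable,
    settings: EconSettings,
    values: Mapping[str, float] | None = None,
) -> CostAccumulator:
    """Discounted total cost of one arm over the model horizon.

    Per cycle k: drug cost = sum over scheduled drugs of
    [k < cap] * unit_cost * p_pfs(k); imaging = imaging_cost * p_pfs(k);
    follow-up = mix cost * p_pd(k); all discounted at the cost factor.
    The expected adverse-event cost is added once at cycle 0.
    """
    k = trace.cycle_index
    disc = trace.disc_factor_costs
    pfs_disc = trace.p_pfs * disc
    pd_disc = trace.p_pd * disc

    drug = 0.0
    for line in arm.drug_schedule:
        unit = _val(values, f"cost.drug.{line.drug}",
                    costs.per_cycle_drug_costs[line.drug].base)
        on = pfs_disc if line.max_cycles is None else pfs_disc[k < line.max_cycles]
        drug += unit * float(np.sum(on))

    imaging_unit = _val(values, "cost.imaging_pfs", costs.imaging_cost_pfs.base)
    imaging = imaging_unit * float(np.sum(pfs_disc))
    followup = followup_cost_per_cycle(arm, costs, values) * float(np.sum(pd_disc))
    ae = expected_ae_cost(arm, costs, values) * float(disc[0])
    return CostAccumulator(
        drug_cost=drug, imaging_cost=imaging, ae_cost=ae, followup_cost=followup
    )


def cost_breakdown_frame(acc: CostAccumulator, arm_label: str):
    """Tidy per-component cost table (discounted USD)."""
    import pandas as pd

    rows = [
        {"arm": arm_label, "component": c, "discounted": getattr(acc, f"{c}_cost")}
        for c in ("drug", "imaging", "ae", "followup")
    ]
    rows.append({"arm": arm_label, "component": "total", "discounted": acc.total_disc})
    return pd.DataFrame(rows)
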