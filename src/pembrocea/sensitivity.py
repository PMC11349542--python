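"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis moves each parameter to the low and high end of its
stated range (or +/-25% of base where none is published) with everything
else held at base, recording the two ICERs; entries are ranked by bar
width.  The probabilistic analysis is a second-order Monte Carlo: every
uncertain parameter is drawn jointly — gamma for costs, beta for
utilities and probabilities, moment-matched so the mean equals the base
value and the standard deviation treats the published range as a 95%
interval, sd = (high - low)/3.92 — and the full model is re-evaluated per
draw.  The cost-effectiveness acceptability curve (CEAC) reports, per
willingness-to-pay value, the fraction of draws with positive net
monetary benefit.

Survival-curve parameters and the discount rate carry no published
distribution and are held fixed in the probabilistic analysis; the
discount rate does enter the tornado.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .cea import evaluate_model
from .config import ModelConfig, ParamRange

__all__ = ["one_way_sa", "draw_parameters", "run_psa", "ceac_from_samples"]


def one_way_sa(
    config: ModelConfig,
    params: Sequence[ParamRange] | None = None,
    sd_rule: str = "range95",
) -> pd.DataFrame:
    """Tornado table: columns param, base, low, high, icer_at_low,
    icer_at_high, width, note; sorted by width descending.

    A parameter extreme under which the model fails (or the ICER is
    undefined by dominance) is flagged in ``note`` and the run continues.
    """
    if params is None:
        params = config.param_ranges()
    base_res = evaluate_model(config)
    rows = []
    for p in params:
        icers = {}
        notes = []
        for side, value in (("low", p.low), ("high", p.high)):
            try:
                res = evaluate_model(config, {p.name: value})
                icer = res.icer_qaly
                if icer is None:
                    notes.append(f"{side}:{res.dominance}")
                icers[side] = np.nan if icer is None else icer
            except Exception as exc:  # model failure at an extreme
                notes.append(f"{side}:failed({exc})")
                icers[side] = np.nan
        width = (
            abs(icers["high"] - icers["low"])
            if np.isfinite(icers["low"]) and np.isfinite(icers["high"])
            else np.nan
        )
        rows.append(
            {
                "param": p.name,
                "base": p.base,
                "low": p.low,
                "high": p.high,
                "icer_at_low": icers["low"],
                "icer_at_high": icers["high"],
                "width": width,
                "note": ";".join(notes),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        "width", ascending=False, na_position="last", kind="stable"
    )
    df.attrs["base_icer"] = base_res.icer_qaly
    return df.reset_index(drop=True)


def _moment_match_sd(p: ParamRange, sd_rule: str) -> float:
    if sd_rule == "range95":
        return (p.high - p.low) / 3.92
    if sd_rule == "cv25":
        return 0.25 * abs(p.base)
    raise ValueError(f"unknown sd_rule {sd_rule!r}")


def _draw_one(p: ParamRange, rng: np.random.Generator, n: int, sd_rule: str) -> np.ndarray:
    sd = _moment_match_sd(p, sd_rule)
    if sd == 0 or p.distribution_family is None:
        return np.full(n, p.base)
    if p.distribution_family == "gamma":
        m = p.base
        if m <= 0:
            return np.full(n, m)
        shape = (m / sd) ** 2
        scale = sd * sd / m
        return rng.gamma(shape, scale, size=n)
    if p.distribution_family == "beta":
        # beta on the magnitude scale; disutilities are re-signed after
        m = abs(p.base)
        sign = -1.0 if p.base < 0 else 1.0
        if not (0.0 < m < 1.0):
            raise ValueError(
                f"{p.name}: beta requires a base magnitude in (0, 1), got {m}"
            )
        v = sd * sd
        if v >= m * (1 - m):
            raise ValueError(f"{p.name}: range too wide for a beta distribution")
        nu = m * (1 - m) / v - 1.0
        return sign * rng.beta(m * nu, (1 - m) * nu, size=n)
    raise AssertionError(p.distribution_family)


def draw_parameters(
    params: Sequence[ParamRange],
    seed: int,
    n: int,
    sd_rule: str = "range95",
) -> pd.DataFrame:
    """Joint parameter draws, one column per parameter.

    Columns are drawn in sorted-name order from a single seeded generator,
    so the draw matrix is independent of the order ``params`` is supplied
    in and identical under the same seed.
    """
    rng = np.random.default_rng(seed)
    by_name = {p.name: p for p in params}
    if len(by_name) != len(params):
        raise ValueError("duplicate parameter names")
    cols = {
        name: _draw_one(by_name[name], rng, n, sd_rule) for name in sorted(by_name)
    }
    df = pd.DataFrame(cols)
    df.insert(0, "draw", np.arange(n))
    return df


def ceac_from_samples(samples: pd.DataFrame, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """CEAC(w) = fraction of draws with w*dQALY - dCost > 0."""
    dq = samples["incr_qaly"].to_numpy(float)
    dc = samples["incr_cost"].to_numpy(float)
    rows = [
        {"wtp": float(w), "probability": float(np.mean(w * dq - dc > 0))}
        for w in wtp_grid
    ]
    return pd.DataFrame(rows)


def run_psa(
    config: ModelConfig,
    n: int = 1000,
    seed: int = 0,
    wtp_grid: Sequence[float] | None = None,
    sd_rule: str = "range95",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Second-order Monte Carlo over every parameter with a published
    distribution (costs: gamma; utilities/probabilities: beta).

    Returns ``(samples, ceac)``: per-draw parameter values with incremental
    cost, incremental QALY and net monetary benefit at the country WTP, and
    the CEAC on ``wtp_grid`` (default: 0 to 2,000,000 in 61 steps, with the
    country threshold inserted).  Draws yielding non-finite model output are
    rejected and replaced (count in ``samples.attrs['n_rejected']``).
    """
    params = [p for p in config.param_ranges() if p.distribution_family is not None]
    wtp = config.settings.wtp_per_qaly
    if wtp_grid is None:
        grid = np.linspace(0.0, 2_000_000.0, 61)
        wtp_grid = np.unique(np.append(grid, wtp))

    draws = draw_parameters(params, seed, n, sd_rule)
    param_cols = [c for c in draws.columns if c != "draw"]
    rows = []
    n_rejected = 0
    rng_replace = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    i = 0
    attempts = 0
    while i < n and attempts < 10 * n:
        attempts += 1
        overrides = {c: float(draws.at[i, c]) for c in param_cols}
        res = evaluate_model(config, overrides)
        ok = all(
            np.isfinite(v)
            for v in (res.incr_cost, res.incr_qaly, res.comparison.cost)
        )
        if not ok:
            n_rejected += 1
            by_name = {p.name: p for p in params}
            for c in param_cols:  # replacement draw for this row
                draws.at[i, c] = _draw_one(by_name[c], rng_replace, 1, sd_rule)[0]
            continue
        rows.append(
            {
                "draw": i,
                **overrides,
                "incr_cost": res.incr_cost,
                "incr_qaly": res.incr_qaly,
                "nmb_at_wtp": wtp * res.incr_qaly - res.incr_cost,
            }
        )
        i += 1
    samples = pd.DataFrame(rows)
    samples.attrs["n_rejected"] = n_rejected
    samples.attrs["wtp_per_qaly"] = wtp
    ceac = ceac_from_samples(samples, wtp_grid)
    return samples, ceac
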