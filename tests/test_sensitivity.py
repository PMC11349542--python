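"""Tornado analysis and probabilistic sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

from pembrocea import (
    ceac_from_samples,
    draw_parameters,
    evaluate_model,
    one_way_sa,
    run_psa,
)
from pembrocea.config import ParamRange


def test_degenerate_range_gives_zero_width(china):
    p = ParamRange(
        name="cost.imaging_pfs", base=45.27, low=45.27, high=45.27,
        distribution_family="gamma",
    )
    df = one_way_sa(china, [p])
    assert df.loc[0, "width"] == 0.0


def test_tornado_top_parameters_china(china):
    """Pembrolizumab price, the PFS utility and the discount rate are the
    published dominant drivers of the China ICER."""
    df = one_way_sa(china)
    top = set(df.head(6)["param"])
    assert "cost.drug.pembrolizumab" in top
    assert "utility.pfs" in top
    assert "settings.annual_discount_rate" in top
    assert df.loc[0, "param"] == "cost.drug.pembrolizumab"


def test_tornado_linearity_oracle(china):
    """A unit cost enters the incremental cost affinely: the ICER excursion
    equals the analytic slope times the range."""
    p = ParamRange(
        name="cost.ae.anemia", base=213.32, low=159.99, high=266.65,
        distribution_family="gamma",
    )
    df = one_way_sa(china, [p])
    base = evaluate_model(china)
    lo = evaluate_model(china, {p.name: p.low})
    hi = evaluate_model(china, {p.name: p.high})
    slope = (hi.incr_cost - lo.incr_cost) / (p.high - p.low)
    expected = slope * (p.high - p.low) / base.incr_qaly
    got = df.loc[0, "icer_at_high"] - df.loc[0, "icer_at_low"]
    assert got == pytest.approx(expected, rel=1e-9)


def test_tornado_restores_base_case(china):
    before = evaluate_model(china).icer_qaly
    one_way_sa(china)
    after = evaluate_model(china).icer_qaly
    assert after == before  # config is immutable; base case untouched


def test_draws_deterministic_and_order_independent():
    params = [
        ParamRange(name="cost.a", base=100.0, low=50.0, high=150.0, distribution_family="gamma"),
        ParamRange(name="prob.b", base=0.3, low=0.2, high=0.4, distribution_family="beta"),
    ]
    d1 = draw_parameters(params, seed=5, n=100)
    d2 = draw_parameters(params, seed=5, n=100)
    d3 = draw_parameters(params[::-1], seed=5, n=100)
    pd.testing.assert_frame_equal(d1, d2)
    pd.testing.assert_frame_equal(d1, d3)
    assert not d1.equals(draw_parameters(params, seed=6, n=100))


def test_degenerate_range_draws_constant():
    p = ParamRange(name="x", base=2.0, low=2.0, high=2.0, distribution_family="gamma")
    d = draw_parameters([p], seed=1, n=50)
    assert (d["x"] == 2.0).all()


def test_gamma_and_beta_moment_recovery():
    """Moment matching with sd = range/3.92: sample means within 1% of base
    at 10,000 draws; gamma draws positive, beta draws within [0, 1]."""
    g = ParamRange(name="cost.neutropenia", base=354.00, low=265.50, high=442.50,
                   distribution_family="gamma")
    b = ParamRange(name="utility.pfs", base=0.79, low=0.60, high=0.80,
                   distribution_family="beta")
    d = draw_parameters([g, b], seed=3, n=10000)
    assert d[g.name].mean() == pytest.approx(354.00, rel=0.01)
    assert d[b.name].mean() == pytest.approx(0.79, rel=0.01)
    assert (d[g.name] > 0).all()
    assert d[b.name].between(0, 1).all()


def test_beta_draws_resigned_for_disutilities():
    p = ParamRange(name="disutility.neutropenia", base=-0.2, low=-0.25, high=-0.15,
                   distribution_family="beta")
    d = draw_parameters([p], seed=9, n=5000)
    assert (d[p.name] < 0).all()
    assert d[p.name].mean() == pytest.approx(-0.2, rel=0.02)


def test_beta_requires_unit_interval():
    # a beta-distributed quantity must live in the unit interval ...
    with pytest.raises(ValueError, match="beta"):
        ParamRange(name="bad", base=2.0, low=1.5, high=2.5, distribution_family="beta")
    # ... and its range must be narrow enough to moment-match a beta
    p = ParamRange(name="tight", base=0.99, low=0.0, high=1.0, distribution_family="beta")
    with pytest.raises(ValueError, match="too wide"):
        draw_parameters([p], seed=1, n=10)


def test_psa_ceac_monotone_and_limits(china):
    samples, ceac = run_psa(china, n=200, seed=7)
    assert len(samples) == 200
    assert samples.attrs["n_rejected"] == 0
    probs = ceac.sort_values("wtp")["probability"].to_numpy()
    assert np.all(np.diff(probs) >= 0)  # CEAC monotone in WTP
    # at astronomically high WTP the CEAC converges to P(dQALY > 0)
    big = ceac_from_samples(samples, [1e9]).loc[0, "probability"]
    assert big == pytest.approx((samples["incr_qaly"] > 0).mean())


def test_psa_zero_variance_is_step_at_base_icer(china, china_result):
    cfg_params = [
        ParamRange(name=p.name, base=p.base, low=p.base, high=p.base,
                   distribution_family=p.distribution_family)
        for p in china.param_ranges() if p.distribution_family is not None
    ]
    draws = draw_parameters(cfg_params, seed=1, n=20)
    overrides_cols = [c for c in draws.columns if c != "draw"]
    res = [evaluate_model(china, {c: draws.at[i, c] for c in overrides_cols})
           for i in range(3)]
    icers = {round(r.icer_qaly, 6) for r in res}
    assert icers == {round(china_result.icer_qaly, 6)}
    samples = pd.DataFrame({
        "incr_cost": [r.incr_cost for r in res],
        "incr_qaly": [r.incr_qaly for r in res],
    })
    base_icer = china_result.icer_qaly
    below = ceac_from_samples(samples, [base_icer * 0.99]).loc[0, "probability"]
    above = ceac_from_samples(samples, [base_icer * 1.01]).loc[0, "probability"]
    assert (below, above) == (0.0, 1.0)  # step function at the base ICER


def test_psa_mean_increment_near_base_case(china, china_result):
    """With symmetric published ranges the PSA mean incremental QALY sits
    within 3 standard errors of the base case."""
    samples, _ = run_psa(china, n=300, seed=13)
    se = samples["incr_qaly"].std() / np.sqrt(len(samples))
    assert abs(samples["incr_qaly"].mean() - china_result.incr_qaly) < 3 * se
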