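"""Synthetic trial data: right-censored event-time samples and
digitized-curve fixtures.

Every stage of the pipeline (curve reconstruction, parametric fitting,
cohort modelling) can be exercised end-to-end on data generated from the
same parametric families the model extrapolates with — by default the
four fitted KEYNOTE-966 curve shapes (lognormal progression-free survival,
log-logistic overall survival).  Sampling is inverse-CDF throughout
(t = S^-1(U), one code path for all six families; the negative-shape
Gompertz plateau maps sub-plateau U to +inf, which administrative
censoring then truncates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .km import DigitizedCurve, PseudoIPD, km_survival_at
from .survfit import SurvDist

__all__ = [
    "Censoring",
    "SimSpec",
    "generate_ipd",
    "generate_digitized_curve",
    "curve_from_ipd",
    "TABLE_DISTS",
]

#: the four fitted trial distributions (time in months)
TABLE_DISTS = {
    ("pembrolizumab", "PFS"): SurvDist("lognormal", {"meanlog": 1.7765, "sdlog": 1.1090}),
    ("pembrolizumab", "OS"): SurvDist("loglogistic", {"shape": 1.7984, "scale": 12.6047}),
    ("chemotherapy", "PFS"): SurvDist("lognormal", {"meanlog": 1.6558, "sdlog": 1.0038}),
    ("chemotherapy", "OS"): SurvDist("loglogistic", {"shape": 1.8019, "scale": 10.8447}),
}


@dataclass(frozen=True)
class Censoring:
    """Censoring mechanism: 'none', 'admin' (fixed t_max) or 'uniform' on
    (0, t_max)."""

    kind: str = "none"
    t_max: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "admin", "uniform"):
            raise ValueError(f"unknown censoring kind {self.kind!r}")
        if self.kind != "none":
            if self.t_max is None or self.t_max <= 0:
                raise ValueError(f"{self.kind} censoring needs t_max > 0")


@dataclass(frozen=True)
class SimSpec:
    dist: SurvDist
    n_subjects: int
    censor: Censoring = Censoring("none")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def generate_ipd(spec: SimSpec, arm_label: str = "", endpoint: str = "") -> PseudoIPD:
    """Draw right-censored event times; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n_subjects)
    t_event = np.asarray(spec.dist.inverse_survival(u), float)
    if spec.censor.kind == "none":
        c = np.full(spec.n_subjects, np.inf)
    elif spec.censor.kind == "admin":
        c = np.full(spec.n_subjects, float(spec.censor.t_max))
    else:
        c = rng.uniform(0.0, float(spec.censor.t_max), size=spec.n_subjects)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    if np.any(~np.isfinite(time)):
        raise ValueError(
            "sampled times include +inf (plateauing survival without "
            "administrative censoring); add a censoring model"
        )
    return PseudoIPD(time=time, event=event, arm_label=arm_label, endpoint=endpoint)


def generate_digitized_curve(
    dist: SurvDist,
    grid_points: int,
    jitter_sd: float = 0.0,
    seed: int = 0,
    t_max: float = 36.0,
    n_subjects: int = 500,
    at_risk_every: float | None = 6.0,
) -> DigitizedCurve:
    """A stand-in for plot-digitizer output: S(t) on an even grid with
    additive jitter, isotonically clipped, plus at-risk counts derived from
    the exact distribution (administrative censoring at ``t_max``)."""
    if grid_points < 2:
        raise ValueError("grid_points must be >= 2")
    if jitter_sd > 0.005:
        raise ValueError("jitter_sd beyond the monotonicity-repair tolerance 0.005")
    t = np.linspace(0.0, t_max, grid_points)
    s = np.asarray(dist.survival(t), float)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, jitter_sd, size=s.shape)
        s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
        s[0] = 1.0
    at_risk = None
    if at_risk_every is not None:
        taus = np.arange(0.0, t_max, at_risk_every)
        at_risk = [(float(tau), int(round(n_subjects * dist.survival(tau)))) for tau in taus]
    return DigitizedCurve(times=t, survival=s, total_n=n_subjects, at_risk=at_risk)


def curve_from_ipd(
    ipd: PseudoIPD,
    grid_points: int = 200,
    at_risk_every: float | None = 6.0,
) -> DigitizedCurve:
    """Digitize the Kaplan-Meier estimate of an actual sample: the exact KM
    step function sampled on an even grid, with the sample's true at-risk
    counts.  Emulates reading a published curve with its at-risk table."""
    t_max = float(ipd.time.max())
    grid = np.linspace(0.0, t_max, grid_points)
    s = km_survival_at(ipd, grid)
    at_risk = None
    if at_risk_every is not None:
        taus = np.arange(0.0, t_max, at_risk_every)
        at_risk = [(float(tau), int(np.sum(ipd.time >= tau))) for tau in taus]
    return DigitizedCurve(
        times=grid,
        survival=s,
        total_n=len(ipd),
        at_risk=at_risk,
        total_events=ipd.n_events,
    )
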