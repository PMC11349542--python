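"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published trial curves only give the survival *function*; fitting
parametric models needs event and censoring *times*.  This module inverts
the KM steps back into pseudo-IPD with the standard at-risk-constrained
iterative procedure: within each interval between published at-risk
timepoints, a censoring count is found such that walking the curve's steps
(events from the KM ratio, censorings spread uniformly over the interval)
lands exactly on the next published at-risk number.  Without an at-risk
table, no censoring is assumed before the last follow-up time and the
inversion is exact.

Survivors at the end of follow-up are administratively censored at the
last curve time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DigitizedCurve", "PseudoIPD", "reconstruct_ipd", "km_survival_at"]

#: digitization jitter larger than this is an error, smaller is repaired
MONOTONE_REPAIR_TOL = 0.005


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed event/censoring times (months); event=1, censored=0."""

    time: np.ndarray
    event: np.ndarray
    arm_label: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        e = np.asarray(self.event, int)
        if t.shape != e.shape:
            raise ValueError("time and event must have equal length")
        if np.any(t <= 0):
            raise ValueError("all times must be strictly positive")
        if not set(np.unique(e)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)

    def __len__(self) -> int:
        return len(self.time)

    def __getitem__(self, key: str) -> np.ndarray:
        if key in ("time", "event"):
            return getattr(self, key)
        raise KeyError(key)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.time, "event": self.event})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, arm_label: str = "", endpoint: str = "") -> "PseudoIPD":
        df = pd.read_csv(path)
        return cls(
            time=df["time_months"].to_numpy(float),
            event=df["event"].to_numpy(int),
            arm_label=arm_label,
            endpoint=endpoint,
        )


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized (time, survival) coordinates plus at-risk metadata.

    Small digitization jitter (survival increases of at most
    ``MONOTONE_REPAIR_TOL``) is repaired by a non-increasing running-minimum
    projection; larger violations raise.
    """

    times: np.ndarray
    survival: np.ndarray
    total_n: int
    at_risk: list[tuple[float, int]] | None = None
    total_events: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        s = np.asarray(self.survival, float)
        if t.shape != s.shape or t.ndim != 1 or len(t) < 2:
            raise ValueError("times and survival must be 1-d of equal length >= 2")
        if np.any(t < 0) or np.any(np.diff(t) < 0):
            raise ValueError("times must be non-negative and ascending")
        if s[0] > 1 + 1e-9 or np.any(s < -1e-9):
            raise ValueError("survival must lie in [0, 1]")
        rises = np.diff(s)
        if np.any(rises > MONOTONE_REPAIR_TOL):
            i = int(np.argmax(rises > MONOTONE_REPAIR_TOL))
            raise ValueError(
                f"survival increases by {rises[i]:.4f} at index {i + 1}; "
                f"exceeds the digitization-repair tolerance {MONOTONE_REPAIR_TOL}"
            )
        s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
        if self.total_n < 1:
            raise ValueError("total_n must be >= 1")
        if self.at_risk is not None:
            ar = [(float(a), int(b)) for a, b in self.at_risk]
            if any(b0 < b1 for (_, b0), (_, b1) in zip(ar, ar[1:])):
                # at-risk counts must not increase over time
                raise ValueError("at-risk counts must be non-increasing")
            object.__setattr__(self, "at_risk", ar)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)

    @classmethod
    def from_csv(cls, path, total_n: int, at_risk_path=None, total_events=None):
        df = pd.read_csv(path)
        at_risk = None
        if at_risk_path is not None:
            ar = pd.read_csv(at_risk_path)
            at_risk = list(zip(ar["time_months"], ar["n_at_risk"]))
        return cls(
            times=df["time_months"].to_numpy(float),
            survival=df["survival"].to_numpy(float),
            total_n=total_n,
            at_risk=at_risk,
            total_events=total_events,
        )


def km_survival_at(ipd: PseudoIPD, times) -> np.ndarray:
    """Kaplan-Meier estimate from IPD evaluated at ``times`` (step function,
    right-continuous).  Used to verify reconstructions."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter().fit(ipd.time, ipd.event)
    return (
        km.survival_function_at_times(np.asarray(times, float)).to_numpy(float)
    )


def _prepare(curve: DigitizedCurve) -> tuple[np.ndarray, np.ndarray]:
    t, s = curve.times, curve.survival
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    return t, s


def reconstruct_ipd(
    curve: DigitizedCurve, arm_label: str = "", endpoint: str = "", max_iter: int = 100
) -> PseudoIPD:
    """Invert a digitized KM curve into pseudo event/censor times.

    With an at-risk table, the censoring count within each at-risk interval
    is solved iteratively so the implied number at risk matches the next
    published count (censor times spread uniformly within the interval);
    an interval that would require negative censoring raises with the
    interval index.  Without at-risk data, no censoring is assumed before
    the last follow-up time.
    """
    t, s = _prepare(curve)
    m = len(t)

    if curve.at_risk:
        boundaries = list(curve.at_risk)
        if boundaries[0][0] > t[0]:
            boundaries = [(float(t[0]), int(curve.total_n))] + boundaries
    else:
        boundaries = [(float(t[0]), int(curve.total_n))]
    # curve index ranges [lo_j, lo_{j+1}) per at-risk interval
    lows = [int(np.searchsorted(t, tau, side="left")) for tau, _ in boundaries]
    lows = [min(i, m - 1) for i in lows]

    event_times: list[float] = []
    censor_times: list[float] = []
    km_prev = 1.0
    n_cur = float(boundaries[0][1])

    for j, (tau_j, n_j) in enumerate(boundaries):
        lo = lows[j]
        hi = lows[j + 1] if j + 1 < len(boundaries) else m
        tau_next = t[lows[j + 1]] if j + 1 < len(boundaries) else t[-1]
        target_next = boundaries[j + 1][1] if j + 1 < len(boundaries) else None

        c_j = 0
        state = None
        slack = False  # published count off by rounding; keep the walk's n
        for _ in range(max_iter):
            # uniform censor times within (tau_j, tau_next)
            if c_j > 0:
                cens = tau_j + (np.arange(1, c_j + 1) / (c_j + 1)) * (tau_next - tau_j)
            else:
                cens = np.empty(0)
            ev_t: list[float] = []
            ev_d: list[int] = []
            cen_used: list[float] = []
            km_run = km_prev
            n_run = n_cur
            cens_iter = list(cens)
            for i in range(lo, hi):
                if t[i] > 0 and km_run > 0 and n_run >= 1:
                    d = int(round(n_run * (1.0 - s[i] / km_run)))
                    d = max(0, min(d, int(round(n_run))))
                else:
                    d = 0
                if d > 0:
                    km_run *= 1.0 - d / n_run
                    ev_t.append(float(t[i]))
                    ev_d.append(d)
                    n_run -= d
                t_next_pt = t[i + 1] if i + 1 < m else np.inf
                while cens_iter and cens_iter[0] <= t_next_pt and cens_iter[0] > t[i]:
                    cen_used.append(cens_iter.pop(0))
                    n_run -= 1
            n_run -= len(cens_iter)  # censors beyond the last curve point
            cen_used.extend(cens_iter)
            state = (ev_t, ev_d, cen_used, km_run, n_run)
            if target_next is None:
                break
            diff = int(round(n_run - target_next))
            if diff == 0:
                break
            if c_j + diff < 0:
                # the curve's steps alone leave fewer at risk than published;
                # small deficits are digitization/rounding slack, larger ones
                # mean the at-risk table contradicts the curve
                deficit_tol = max(2, int(round(0.01 * curve.total_n)))
                if c_j + diff < -deficit_tol:
                    raise ValueError(
                        f"at-risk counts inconsistent with curve in interval {j}: "
                        f"would need {c_j + diff} censorings"
                    )
                slack = True
                break
            c_j += diff
        ev_t, ev_d, cen_used, km_prev, n_cur = state
        for te, d in zip(ev_t, ev_d):
            event_times.extend([te] * d)
        censor_times.extend(cen_used)
        if target_next is not None and not slack:
            n_cur = float(target_next)

    # administrative censoring of survivors at the end of follow-up
    n_left = int(round(n_cur))
    if n_left > 0:
        censor_times.extend([float(t[-1])] * n_left)

    times = np.concatenate([event_times, censor_times]) if (
        event_times or censor_times
    ) else np.empty(0)
    events = np.concatenate(
        [np.ones(len(event_times), int), np.zeros(len(censor_times), int)]
    )
    order = np.argsort(times, kind="stable")
    return PseudoIPD(
        time=times[order], event=events[order], arm_label=arm_label, endpoint=endpoint
    )
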