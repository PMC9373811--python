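"""Kaplan-Meier / Nelson-Aalen estimators and the log-rank test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist


@dataclass
class StepFunction:
    """Right-continuous step function with a left boundary value."""

    x: np.ndarray
    y: np.ndarray
    left_value: float = 1.0

    def _eval(self, t, side: str):
        t = np.asarray(t, dtype=float)
        if len(self.x) == 0:
            out = np.full(t.shape, self.left_value)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.x, t, side=side) - 1
        out = np.where(idx >= 0, self.y[np.clip(idx, 0, len(self.y) - 1)], self.left_value)
        return out if out.ndim else float(out)

    def __call__(self, t) -> np.ndarray:
        return self._eval(t, "right")

    def evaluate_left(self, t) -> np.ndarray:
        """Left limit, i.e. the value just before t."""
        return self._eval(t, "left")


def _counts(time: np.ndarray, event: np.ndarray):
    """Unique event/censoring times with death and at-risk counts."""
    times = np.unique(time)
    deaths = np.array([np.sum((time == t) & (event == 1)) for t in times])
    at_risk = np.array([np.sum(time >= t) for t in times])
    return times, deaths, at_risk


def km_estimate(time, event) -> StepFunction:
    """Product-limit estimator of the survival function S(t)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("empty group")
    times, deaths, at_risk = _counts(time, event)
    keep = deaths > 0
    surv = np.cumprod(1.0 - deaths[keep] / at_risk[keep])
    return StepFunction(x=times[keep], y=surv, left_value=1.0)


def nelson_aalen(time, event, grid: np.ndarray | None = None):
    """Nelson-Aalen cumulative hazard, optionally evaluated on a fixed grid."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    times, deaths, at_risk = _counts(time, event)
    keep = deaths > 0
    chf = np.cumsum(deaths[keep] / at_risk[keep])
    fn = StepFunction(x=times[keep], y=chf, left_value=0.0)
    if grid is None:
        return fn
    return fn(np.asarray(grid, dtype=float))


def logrank_test(time, event, groups) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi-square, p) with k-1 df.

    For two groups this is the familiar 1-df two-sided test.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if np.sum(groups == lab) == 0:
            raise ValueError(f"empty group {lab!r}")
    event_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = np.sum((time == t) & (event == 1))
        n_g = np.array([np.sum(at_risk & (groups == lab)) for lab in labels])
        d_g = np.array([np.sum((time == t) & (event == 1) & (groups == lab)) for lab in labels])
        O += d_g
        E += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            V += d_t * (n_t - d_t) / (n_t - 1) * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = 0.0
    p = float(chi2_dist.sf(chi2, df=k - 1))
    return chi2, p
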