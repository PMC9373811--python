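"""Performance metrics for survival risk scores.

Convention throughout: a *higher* risk score means a *worse* expected
outcome (shorter survival).
"""

from __future__ import annotations

import warnings

import numpy as np

from .nonparam import km_estimate


def concordance_index(risk, data) -> float:
    """Harrell's C over usable pairs.

    A pair is usable when the shorter observed time carries an event; it is
    concordant when the shorter-lived subject has the higher risk, and risk
    ties count one half.
    """
    risk = np.asarray(risk, dtype=float)
    time, event = data.time, data.event
    n = len(time)
    if risk.shape != (n,):
        raise ValueError("risk must have one entry per subject")
    dt = time[:, None] < time[None, :]
    usable = dt & (event[:, None] == 1)
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("no usable pairs: cannot compute concordance")
    higher = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    concordant = (usable & higher).sum() + 0.5 * (usable & tied).sum()
    return float(concordant / n_usable)


def censoring_km(data):
    """Kaplan-Meier estimate of the censoring distribution G(t)."""
    return km_estimate(data.time, 1 - data.event)


def time_dependent_auc(risk, data, eval_times) -> np.ndarray:
    """Cumulative/dynamic AUC(t) with IPCW weights from the censoring KM.

    Cases at horizon t are subjects with an observed event by t; controls are
    subjects still at risk beyond t.  Case i is weighted by 1/G(T_i-), where
    G is the Kaplan-Meier estimate of the censoring distribution; the control
    weight 1/G(t) is constant and cancels.  Horizons with no cases or no
    controls yield NaN.
    """
    risk = np.asarray(risk, dtype=float)
    eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
    time, event = data.time, data.event
    G = censoring_km(data)
    out = np.full(len(eval_times), np.nan)
    for k, t in enumerate(eval_times):
        cases = (time <= t) & (event == 1)
        controls = time > t
        if cases.sum() == 0 or controls.sum() == 0:
            continue
        g = np.asarray(G.evaluate_left(time[cases]))
        if np.any(g <= 0):
            warnings.warn("zero censoring-survival weight; affected cases dropped")
            keep = g > 0
            if not keep.any():
                continue
            cases_idx = np.flatnonzero(cases)[keep]
            cases = np.zeros_like(cases)
            cases[cases_idx] = True
            g = g[keep]
        w = 1.0 / g
        rc = risk[cases]
        rk = risk[controls]
        greater = (rc[:, None] > rk[None, :]).sum(axis=1)
        ties = (rc[:, None] == rk[None, :]).sum(axis=1)
        num = float(np.sum(w * (greater + 0.5 * ties)))
        den = float(w.sum() * len(rk))
        out[k] = num / den
    return out


def calibration_curve(pred_survival, data, t: float, n_groups: int = 4):
    """Grouped calibration of predicted survival probabilities at horizon t.

    Subjects are binned into ``n_groups`` quantile groups of the predicted
    survival probability; for each group the mean prediction is paired with
    the Kaplan-Meier observed survival at t.  Returns an array of
    (mean_predicted, km_observed, group_size) rows.
    """
    pred = np.asarray(pred_survival, dtype=float)
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if np.all(pred == pred[0]):
        warnings.warn("degenerate predictions (all equal): single calibration bin")
        km = km_estimate(data.time, data.event)
        return np.array([[float(pred[0]), float(km(t)), len(pred)]])
    qs = np.quantile(pred, np.linspace(0, 1, n_groups + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    rows = []
    for lo, hi in zip(qs[:-1], qs[1:]):
        mask = (pred > lo) & (pred <= hi)
        if mask.sum() == 0:
            continue
        km = km_estimate(data.time[mask], data.event[mask])
        rows.append([float(pred[mask].mean()), float(km(t)), int(mask.sum())])
    return np.array(rows)
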