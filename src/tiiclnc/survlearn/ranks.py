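"""Log-rank (Savage) scores and the log-rank score split statistic.

These are the primitives behind survival-tree splitting and maximally
selected cutpoints.  Each subject j with survival time T_j and event
indicator delta_j receives the score

    a_j = delta_j - sum_{k=1}^{Gamma_j} delta_(k) / (n - Gamma_k + 1)

where subjects are ordered by time (ties broken by stable original order,
so Gamma_k is simply the rank k under that order).  For a candidate split
of an ordered covariate x at cutpoint c, with L = {j : x_j <= c} and
n1 = |L|, the standardized node-separation statistic is

    S(x, c) = (sum_{j in L} a_j - n1 * a_bar) / sqrt(n1 (1 - n1/n) s_a^2)

and the best split maximizes |S(x, c)| over variables and cutpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SurvivalData


@dataclass
class LogRankScoreSet:
    """Per-subject log-rank scores in original subject order."""

    a: np.ndarray        # score per subject, original order
    gamma: np.ndarray    # rank of each subject under the (time, index) order
    mean: float          # sample mean of the scores
    var: float           # sample variance (ddof=1) of the scores


def logrank_scores(data: SurvivalData) -> LogRankScoreSet:
    """Compute log-rank scores for every subject.

    With no censoring the scores sum to zero (a property test); ties in time
    are broken by original subject index, recorded through ``gamma``.
    """
    n = data.n
    if n < 2:
        raise ValueError("need at least two subjects")
    order = np.lexsort((np.arange(n), data.time))
    d_sorted = data.event[order].astype(float)
    ranks = np.arange(1, n + 1)
    cum = np.cumsum(d_sorted / (n - ranks + 1))
    a_sorted = d_sorted - cum
    a = np.empty(n)
    a[order] = a_sorted
    gamma = np.empty(n, dtype=int)
    gamma[order] = ranks
    return LogRankScoreSet(a=a, gamma=gamma, mean=float(a.mean()), var=float(a.var(ddof=1)))


def logrank_score_split(x: np.ndarray, scores: LogRankScoreSet, c: float) -> float:
    """Signed split statistic S(x, c) for the group {x <= c} vs the rest.

    Raises if the scores have zero variance (the node is pure and must be
    terminal) or if one side of the cutpoint is empty.
    """
    x = np.asarray(x, dtype=float)
    a = scores.a
    n = len(a)
    left = x <= c
    n1 = int(left.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("cutpoint leaves one side empty")
    if scores.var <= 0:
        raise ValueError("zero score variance: split undefined")
    num = a[left].sum() - n1 * scores.mean
    den = np.sqrt(n1 * (1 - n1 / n) * scores.var)
    return float(num / den)


def best_split(
    x: np.ndarray,
    scores: LogRankScoreSet,
    min_leaf: int = 1,
) -> tuple[float, float] | None:
    """Maximize |S(x, c)| over midpoints of consecutive distinct x values.

    Only cutpoints leaving at least ``min_leaf`` subjects on each side are
    considered.  Returns ``(cutpoint, S)`` for the best candidate, preferring
    the lower cutpoint on exact ties, or None when no valid cutpoint exists.
    """
    x = np.asarray(x, dtype=float)
    a = scores.a
    n = len(a)
    if scores.var <= 0:
        return None
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    prefix = np.cumsum(a[order])
    # candidate boundary after position i (0-based): left size i+1
    n1 = np.arange(1, n)
    valid = (xs[:-1] < xs[1:]) & (n1 >= min_leaf) & (n - n1 >= min_leaf)
    if not valid.any():
        return None
    num = prefix[:-1] - n1 * scores.mean
    den = np.sqrt(n1 * (1 - n1 / n) * scores.var)
    s_all = np.where(valid, num / den, 0.0)
    abs_s = np.abs(s_all)
    best = int(np.argmax(np.where(valid, abs_s, -np.inf)))
    cut = 0.5 * (xs[best] + xs[best + 1])
    return float(cut), float(s_all[best])
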