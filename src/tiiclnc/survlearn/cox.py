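"""Cox proportional-hazards fitting: Newton-Raphson, elastic net, stepwise.

The partial likelihood uses Efron's tie correction throughout.  The
penalized fit is a proximal-Newton scheme: at each outer step the partial
log-likelihood is replaced by its local quadratic model (exact gradient and
Hessian) and the elastic-net penalized quadratic is solved by cyclic
coordinate descent with soft-thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr


def efron_loglik(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    beta: np.ndarray,
    offset: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron-corrected Cox partial log-likelihood, gradient and information.

    Returns ``(loglik, gradient, information)`` where information is the
    negative Hessian (positive semidefinite).  ``offset`` is a fixed
    per-subject addition to the linear predictor (used by boosting).
    """
    n, p = X.shape
    eta = X @ beta
    if offset is not None:
        eta = eta + offset
    eta = eta - eta.max()  # guard exp overflow; cancels in all ratios
    w = np.exp(eta)

    order = np.argsort(-time, kind="mergesort")  # descending time
    t_s, d_s = time[order], event[order]
    X_s, w_s, eta_s = X[order], w[order], eta[order]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))

    i = 0
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        block = slice(i, j)
        Xb, wb = X_s[block], w_s[block]
        S0 += wb.sum()
        S1 += wb @ Xb
        S2 += (Xb * wb[:, None]).T @ Xb
        ev = d_s[block] == 1
        d = int(ev.sum())
        if d > 0:
            Xd, wd = Xb[ev], wb[ev]
            D0 = wd.sum()
            D1 = wd @ Xd
            D2 = (Xd * wd[:, None]).T @ Xd
            ll += eta_s[block][ev].sum()
            grad += Xd.sum(axis=0)
            for l in range(d):
                f = l / d
                R0 = S0 - f * D0
                R1 = S1 - f * D1
                R2 = S2 - f * D2
                ll -= np.log(R0)
                mu = R1 / R0
                grad -= mu
                info += R2 / R0 - np.outer(mu, mu)
        i = j
    return float(ll), grad, info


@dataclass
class FittedCox:
    """A fitted Cox model with Wald inference."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_events: int
    feature_names: list[str] | None = None

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def wald_z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se > 0, self.beta / self.se, np.nan)

    @property
    def wald_p(self) -> np.ndarray:
        return 2.0 * (1.0 - ndtr(np.abs(self.wald_z)))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        lo = np.exp(self.beta - z * self.se)
        hi = np.exp(self.beta + z * self.se)
        return np.column_stack([lo, hi])

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.beta)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Linear risk score (log relative hazard)."""
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.beta


def fit_cox(
    data,
    covariates=None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> FittedCox:
    """Newton-Raphson maximization of the Efron partial likelihood.

    ``covariates`` optionally restricts the fit to a column subset.
    Convergence requires max |score| < ``tol``; monotone-likelihood
    (separation-like) behavior is flagged as non-converged.
    """
    if data.n_events < 2:
        raise ValueError("need at least two observed events")
    X = data.covariates
    names = data.feature_names
    if covariates is not None:
        cols = np.asarray(covariates, dtype=int)
        X = X[:, cols] if len(cols) else X[:, :0]
        if names is not None:
            names = [names[int(c)] for c in cols]
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    ll, g, I = efron_loglik(X, data.time, data.event, beta)
    for _ in range(max_iter):
        if p == 0 or np.max(np.abs(g)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(I + 1e-12 * np.eye(p), g)
        except np.linalg.LinAlgError:
            break
        # step-halving to guarantee likelihood ascent
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, g_new, I_new = efron_loglik(X, data.time, data.event, cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, g, I = cand, ll_new, g_new, I_new
        if np.max(np.abs(beta)) > 50:
            converged = False  # monotone likelihood / separation
            break
    if p > 0:
        try:
            cov = np.linalg.inv(I + 1e-12 * np.eye(p))
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
            converged = False
        # a flat likelihood at an extreme estimate signals monotone likelihood
        if np.max(np.abs(beta)) > 20 or np.any(se > 1e3):
            converged = False
    else:
        se = np.zeros(0)
        converged = True
    return FittedCox(beta=beta, se=se, loglik=ll, converged=converged,
                     n_events=data.n_events, feature_names=names)


def breslow_baseline(data, risk):
    """Breslow estimate of the cumulative baseline hazard given linear scores.

    Returns a right-continuous step function H0(t); the predicted survival of
    a subject with score eta is exp(-H0(t) * exp(eta)).
    """
    from .nonparam import StepFunction

    risk = np.asarray(risk, dtype=float)
    w = np.exp(risk - risk.max())
    times = np.unique(data.time[data.event == 1])
    h0 = np.empty(len(times))
    for k, t in enumerate(times):
        d = np.sum((data.time == t) & (data.event == 1))
        h0[k] = d / w[data.time >= t].sum()
    # the max-shift cancels: scale H0 back so that H0 * exp(risk) is invariant
    return StepFunction(x=times, y=np.cumsum(h0) * np.exp(-risk.max()), left_value=0.0)


# ---------------------------------------------------------------------------
# Elastic net


def _soft(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


@dataclass
class PenalizedCox:
    """Elastic-net penalized Cox fit (coefficients on the original scale)."""

    beta: np.ndarray            # original covariate scale
    beta_std: np.ndarray        # standardized-covariate scale (penalized scale)
    alpha: float
    lam: float
    converged: bool
    n_iter: int
    center: np.ndarray
    scale: np.ndarray
    feature_names: list[str] | None = None

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.beta_std != 0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return ((X - self.center) / self.scale) @ self.beta_std


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - center) / scale, center, scale


def lambda_max(data, alpha: float = 1.0) -> float:
    """Smallest penalty for which the lasso/enet solution is all-zero."""
    Z, _, _ = _standardize(data.covariates)
    _, g, _ = efron_loglik(Z, data.time, data.event, np.zeros(data.p))
    return float(np.max(np.abs(g)) / max(alpha, 1e-3))


def fit_penalized_cox(
    data,
    alpha: float,
    lam: float,
    max_outer: int = 100,
    tol: float = 1e-7,
    beta_init: np.ndarray | None = None,
) -> PenalizedCox:
    """Elastic-net Cox: penalty lam * (alpha*|b|_1 + (1-alpha)*|b|_2^2 / 2).

    alpha=1 is the lasso, alpha=0 the ridge.  Covariates are standardized
    internally (the penalty acts on the standardized scale); at lam=0 the fit
    coincides with the unpenalized Newton-Raphson solution.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    Z, center, scale = _standardize(data.covariates)
    n, p = Z.shape
    beta = np.zeros(p) if beta_init is None else beta_init.copy()
    converged = False
    it = 0
    for it in range(1, max_outer + 1):
        ll, g, I = efron_loglik(Z, data.time, data.event, beta)
        diag = np.diag(I).copy()
        diag = np.where(diag > 1e-10, diag, 1e-10)
        b = beta.copy()
        for _ in range(200):
            max_delta = 0.0
            for j in range(p):
                # c_j = g_j + I_jj*beta0_j - sum_{k!=j} I_jk (b_k - beta0_k)
                cj = g[j] + I[j, j] * beta[j] - (I[j] @ (b - beta) - I[j, j] * (b[j] - beta[j]))
                new = _soft(cj, lam * alpha) / (diag[j] + lam * (1 - alpha))
                max_delta = max(max_delta, abs(new - b[j]))
                b[j] = new
            if max_delta < tol / 10:
                break
        if np.max(np.abs(b - beta)) < tol:
            beta = b
            converged = True
            break
        beta = b
    beta_orig = beta / scale
    return PenalizedCox(beta=beta_orig, beta_std=beta, alpha=alpha, lam=lam,
                        converged=converged, n_iter=it, center=center, scale=scale,
                        feature_names=data.feature_names)


def penalized_cox_path(data, alpha: float, lambdas: np.ndarray) -> list[PenalizedCox]:
    """Warm-started solution path over a decreasing lambda sequence."""
    fits: list[PenalizedCox] = []
    beta = None
    for lam in np.sort(np.asarray(lambdas, dtype=float))[::-1]:
        fit = fit_penalized_cox(data, alpha=alpha, lam=float(lam), beta_init=beta)
        beta = fit.beta_std
        fits.append(fit)
    return fits


# ---------------------------------------------------------------------------
# Stepwise selection


def stepwise_cox(data, direction: str = "both", max_covariates: int = 50):
    """Greedy AIC-minimizing covariate selection.

    Returns ``(selected_indices, FittedCox)``.  Ties are broken by covariate
    order, which makes the procedure deterministic.  Guarded to p <= 50: for
    wider matrices pre-select features first.
    """
    if direction not in {"forward", "backward", "both"}:
        raise ValueError(f"unknown direction {direction!r}")
    p = data.p
    if p > max_covariates:
        raise ValueError(f"stepwise_cox guard: p={p} > {max_covariates}; pre-select features")

    def aic_of(cols: tuple[int, ...]) -> tuple[float, FittedCox]:
        fit = fit_cox(data, covariates=list(cols))
        return fit.aic, fit

    current: tuple[int, ...] = tuple(range(p)) if direction == "backward" else ()
    best_aic, best_fit = aic_of(current)
    allow_add = direction in {"forward", "both"}
    allow_drop = direction in {"backward", "both"}
    while True:
        moves: list[tuple[float, tuple[int, ...], FittedCox]] = []
        if allow_add:
            for j in range(p):
                if j not in current:
                    cand = tuple(sorted(current + (j,)))
                    a, f = aic_of(cand)
                    moves.append((a, cand, f))
        if allow_drop:
            for j in current:
                cand = tuple(k for k in current if k != j)
                a, f = aic_of(cand)
                moves.append((a, cand, f))
        if not moves:
            break
        a, cand, f = min(moves, key=lambda m: m[0])  # stable: first minimum wins
        if a < best_aic - 1e-10:
            best_aic, best_fit, current = a, f, cand
        else:
            break
    return list(current), best_fit
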