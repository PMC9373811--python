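"""Random survival forest with log-rank score splitting.

Trees are grown on bootstrap samples.  At each node, ``mtry`` candidate
variables are drawn; for each, log-rank scores a_j are computed from the
node's survival data and the standardized statistic S(x, c) is evaluated at
every midpoint of consecutive distinct covariate values.  The split
maximizing |S(x, c)| over variables and cutpoints is taken (the node becomes
terminal when no admissible split exists).  Terminal nodes carry the
Nelson-Aalen cumulative hazard of their bootstrap subjects on the shared
grid of training event times; a subject's risk score is the ensemble
mortality: the forest-averaged cumulative hazard summed over that grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SurvivalData
from .metrics import concordance_index
from .nonparam import nelson_aalen
from .ranks import logrank_scores, best_split


@dataclass
class RSFModel:
    trees: list[dict]
    inbag: list[np.ndarray]          # bootstrap index arrays, one per tree
    event_time_grid: np.ndarray
    n_trees: int
    mtry: int
    nodesize: int
    seed: int
    feature_names: list[str] | None = None

    def to_dict(self) -> dict:
        return {
            "trees": self.trees,
            "inbag": [ib.tolist() for ib in self.inbag],
            "event_time_grid": self.event_time_grid.tolist(),
            "n_trees": self.n_trees,
            "mtry": self.mtry,
            "nodesize": self.nodesize,
            "seed": self.seed,
            "feature_names": self.feature_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RSFModel":
        return cls(
            trees=d["trees"],
            inbag=[np.asarray(ib, dtype=int) for ib in d["inbag"]],
            event_time_grid=np.asarray(d["event_time_grid"], dtype=float),
            n_trees=d["n_trees"], mtry=d["mtry"], nodesize=d["nodesize"],
            seed=d["seed"], feature_names=d.get("feature_names"),
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_rsf(self, X)


def _grow(node_idx, data, grid, mtry, nodesize, rng):
    """Recursively grow one tree; returns a nested-dict node."""
    time = data.time[node_idx]
    event = data.event[node_idx]
    n_node = len(node_idx)
    can_split = n_node >= 2 * nodesize and event.sum() > 0
    if can_split:
        node_data = SurvivalData(time, event, np.zeros((n_node, 0)))
        scores = logrank_scores(node_data)
        if scores.var > 0:
            p = data.p
            candidates = rng.choice(p, size=min(mtry, p), replace=False)
            best = None  # (|S|, var, cut, S)
            for var in candidates:
                found = best_split(data.covariates[node_idx, var], scores, min_leaf=nodesize)
                if found is None:
                    continue
                cut, s = found
                if best is None or abs(s) > best[0] + 1e-12:
                    best = (abs(s), int(var), cut, s)
            if best is not None:
                _, var, cut, s = best
                left = node_idx[data.covariates[node_idx, var] <= cut]
                right = node_idx[data.covariates[node_idx, var] > cut]
                return {
                    "var": var,
                    "cut": cut,
                    "stat": s,
                    "left": _grow(left, data, grid, mtry, nodesize, rng),
                    "right": _grow(right, data, grid, mtry, nodesize, rng),
                }
    chf = nelson_aalen(time, event, grid=grid)
    return {"chf": np.asarray(chf).tolist(), "size": int(n_node)}


def fit_rsf(
    data: SurvivalData,
    n_trees: int = 1000,
    mtry: int | None = None,
    nodesize: int = 15,
    seed: int = 0,
) -> RSFModel:
    """Fit a random survival forest.

    Defaults follow reference RSF conventions: mtry = ceil(sqrt(p)),
    nodesize 15.  All randomness (bootstraps, variable sampling) derives
    from ``seed``.
    """
    if data.p == 0:
        raise ValueError("no covariates")
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(data.p)))
    if mtry > data.p:
        raise ValueError(f"mtry={mtry} exceeds number of covariates {data.p}")
    rng = np.random.default_rng(seed)
    grid = np.unique(data.time[data.event == 1])
    if len(grid) == 0:
        raise ValueError("no observed events")
    trees, inbag = [], []
    root_warning = 0
    for _ in range(n_trees):
        idx = rng.integers(0, data.n, size=data.n)
        tree = _grow(idx, data, grid, mtry, nodesize, rng)
        if "var" not in tree:
            root_warning += 1
        trees.append(tree)
        inbag.append(idx)
    if root_warning == n_trees:
        import warnings

        warnings.warn("no valid split at any root: forest consists of single-node trees")
    return RSFModel(trees=trees, inbag=inbag, event_time_grid=grid,
                    n_trees=n_trees, mtry=mtry, nodesize=nodesize, seed=seed,
                    feature_names=data.feature_names)


def _tree_chf(tree: dict, x: np.ndarray) -> np.ndarray:
    node = tree
    while "var" in node:
        node = node["left"] if x[node["var"]] <= node["cut"] else node["right"]
    return np.asarray(node["chf"], dtype=float)


def _forest_chf(model: RSFModel, X: np.ndarray, tree_subsets=None) -> np.ndarray:
    """Average CHF per subject over (optionally per-subject subsets of) trees."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    g = len(model.event_time_grid)
    out = np.zeros((n, g))
    counts = np.zeros(n)
    for t_idx, tree in enumerate(model.trees):
        if tree_subsets is None:
            members = range(n)
        else:
            members = np.flatnonzero(tree_subsets[:, t_idx])
        for i in members:
            out[i] += _tree_chf(tree, X[i])
            counts[i] += 1
    with np.errstate(invalid="ignore"):
        out = out / counts[:, None]
    return out


def predict_rsf(model: RSFModel, X: np.ndarray) -> np.ndarray:
    """Ensemble mortality risk score: averaged CHF summed over event times."""
    return _forest_chf(model, X).sum(axis=1)


def _oob_matrix(model: RSFModel, n: int) -> np.ndarray:
    oob = np.ones((n, model.n_trees), dtype=bool)
    for t, idx in enumerate(model.inbag):
        oob[np.unique(idx), t] = False
    return oob


def oob_predict(model: RSFModel, data: SurvivalData) -> np.ndarray:
    """Out-of-bag ensemble mortality (NaN for subjects in every bootstrap)."""
    oob = _oob_matrix(model, data.n)
    chf = _forest_chf(model, data.covariates, tree_subsets=oob)
    return chf.sum(axis=1)


def oob_cindex(model: RSFModel, data: SurvivalData) -> float:
    risk = oob_predict(model, data)
    ok = ~np.isnan(risk)
    return concordance_index(risk[ok], data.subset(np.flatnonzero(ok)))


def oob_error_curve(model: RSFModel, data: SurvivalData, every: int = 1) -> np.ndarray:
    """OOB error (1 - OOB C-index) as trees are added, for the error-vs-trees plot.

    Returns rows of (n_trees_used, oob_error); evaluated every ``every`` trees.
    """
    oob = _oob_matrix(model, data.n)
    n, g = data.n, len(model.event_time_grid)
    cum = np.zeros((n, g))
    counts = np.zeros(n)
    rows = []
    for t, tree in enumerate(model.trees):
        members = np.flatnonzero(oob[:, t])
        for i in members:
            cum[i] += _tree_chf(tree, data.covariates[i])
        counts[members] += 1
        if (t + 1) % every == 0 or t == model.n_trees - 1:
            ok = counts > 0
            if ok.sum() < 2 or data.event[ok].sum() == 0:
                continue
            risk = (cum[ok] / counts[ok, None]).sum(axis=1)
            try:
                c = concordance_index(risk, data.subset(np.flatnonzero(ok)))
            except ValueError:
                continue
            rows.append([t + 1, 1.0 - c])
    return np.array(rows)


def variable_importance(model: RSFModel, data: SurvivalData, seed: int = 0) -> np.ndarray:
    """Permutation importance: drop in OOB C-index after permuting each covariate."""
    base = oob_cindex(model, data)
    rng = np.random.default_rng(seed)
    imp = np.zeros(data.p)
    oob = _oob_matrix(model, data.n)
    for j in range(data.p):
        Xp = data.covariates.copy()
        Xp[:, j] = Xp[rng.permutation(data.n), j]
        chf = _forest_chf(model, Xp, tree_subsets=oob)
        risk = chf.sum(axis=1)
        ok = ~np.isnan(risk)
        c = concordance_index(risk[ok], data.subset(np.flatnonzero(ok)))
        imp[j] = base - c
    return imp
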