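"""Learner-combination harness: enumerate, cross-validate, select, apply.

The prognostic signature is chosen by composing survival learners: every
registered predictor runs alone, and every feature-selecting learner
(lasso, stepwise Cox, CoxBoost, RSF) is composed with every predictor of a
different family.  Each combination is trained on the training cohort
(hyperparameters by k-fold cross-validation, selector on the full training
data, predictor refit on the selected features) and ranked by its mean
concordance index across the validation cohorts.  The winning combination
is refit into a serializable :class:`SignatureModel` that scores external
cohorts, stratifies them at a maximally selected log-rank cutpoint, and is
compared against immunotherapy response labels.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survlearn import (
    SurvivalData,
    concordance_index,
    fit_cox,
    fit_coxboost,
    cv_coxboost_steps,
    fit_penalized_cox,
    fit_rsf,
    lambda_max,
    logrank_scores,
    logrank_test,
    km_estimate,
    predict_rsf,
    stepwise_cox,
    stratified_folds,
    variable_importance,
    RSFModel,
)

SELECTOR_FAMILIES = ("lasso", "stepwise", "coxboost", "rsf")


# ---------------------------------------------------------------------------
# Registry


@dataclass(frozen=True)
class LearnerSpec:
    """One algorithm (and hyper-variant) with its roles in the harness."""

    id: str
    family: str
    roles: frozenset
    params: dict = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if not self.roles:
            raise ValueError("learner needs at least one role")
        if not self.roles <= {"selector", "predictor"}:
            raise ValueError(f"unknown roles {self.roles}")


def default_registry(
    enet_alphas=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    stepwise_directions=("forward", "backward", "both"),
    rsf_trees: int = 200,
) -> dict[str, LearnerSpec]:
    """All implemented algorithm families with their enumerable variants.

    plsRcox, SuperPC, GBM and survival-SVM slots can be registered by the
    caller with the same :class:`LearnerSpec` interface; the harness runs
    with any subset.
    """
    specs = [
        LearnerSpec("lasso", "lasso", frozenset({"selector", "predictor"})),
        LearnerSpec("ridge", "ridge", frozenset({"predictor"})),
        LearnerSpec("coxboost", "coxboost", frozenset({"selector", "predictor"})),
        LearnerSpec("rsf", "rsf", frozenset({"selector", "predictor"}),
                    {"n_trees": rsf_trees, "nodesize": 15}),
    ]
    for a in enet_alphas:
        specs.append(LearnerSpec(f"enet[{a:g}]", "enet", frozenset({"predictor"}),
                                 {"alpha": float(a)}))
    for d in stepwise_directions:
        specs.append(LearnerSpec(f"stepwise[{d}]", "stepwise",
                                 frozenset({"selector", "predictor"}),
                                 {"direction": d}))
    return {s.id: s for s in specs}


def compact_registry(rsf_trees: int = 200) -> dict[str, LearnerSpec]:
    """One variant per family; the registry used by the pipeline defaults."""
    return default_registry(enet_alphas=(0.5,), stepwise_directions=("both",),
                            rsf_trees=rsf_trees)


@dataclass(frozen=True)
class ComboSpec:
    selector: str | None
    predictor: str

    @property
    def id(self) -> str:
        return self.predictor if self.selector is None else f"{self.selector}+{self.predictor}"


def enumerate_combinations(registry: dict[str, LearnerSpec]) -> list[ComboSpec]:
    """Singles plus selector-predictor compositions across families.

    Deterministic (lexicographic by combination identifier).
    """
    predictors = [s for s in registry.values() if "predictor" in s.roles]
    if not predictors:
        raise ValueError("registry has no predictor")
    selectors = [s for s in registry.values()
                 if "selector" in s.roles and s.family in SELECTOR_FAMILIES]
    combos = [ComboSpec(None, p.id) for p in predictors]
    combos += [
        ComboSpec(s.id, p.id)
        for s in selectors for p in predictors
        if s.family != p.family
    ]
    return sorted(combos, key=lambda c: c.id)


# ---------------------------------------------------------------------------
# Fitting one learner (uniform predict + serializable payload)


@dataclass
class FittedLearner:
    """A fitted predictor reduced to a serializable payload."""

    spec_id: str
    kind: str        # "linear" or "rsf"
    payload: dict

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kind == "linear":
            beta = np.asarray(self.payload["beta"], dtype=float)
            center = np.asarray(self.payload["center"], dtype=float)
            scale = np.asarray(self.payload["scale"], dtype=float)
            return ((X - center) / scale) @ beta
        if self.kind == "rsf":
            return predict_rsf(RSFModel.from_dict(self.payload), X)
        raise ValueError(f"unknown learner kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {"spec_id": self.spec_id, "kind": self.kind, "payload": self.payload}

    @classmethod
    def from_dict(cls, d: dict) -> "FittedLearner":
        return cls(spec_id=d["spec_id"], kind=d["kind"], payload=d["payload"])


def _linear_payload(beta, center=None, scale=None) -> dict:
    p = len(beta)
    return {
        "beta": np.asarray(beta, dtype=float).tolist(),
        "center": (np.zeros(p) if center is None else np.asarray(center)).tolist(),
        "scale": (np.ones(p) if scale is None else np.asarray(scale)).tolist(),
    }


def _cv_cindex(fit_fn, data: SurvivalData, k: int, seed: int) -> float:
    """Mean held-out C-index of ``fit_fn`` over event-stratified folds."""
    folds = stratified_folds(data.event, k=k, seed=seed)
    scores = []
    for fold in range(k):
        test = np.flatnonzero(folds == fold)
        train = np.flatnonzero(folds != fold)
        if data.event[test].sum() == 0 or data.event[train].sum() < 2:
            continue
        model = fit_fn(data.subset(train))
        risk = model.predict(data.covariates[test])
        try:
            scores.append(concordance_index(risk, data.subset(test)))
        except ValueError:
            continue
    return float(np.mean(scores)) if scores else np.nan


def fit_learner(spec: LearnerSpec, data: SurvivalData, k: int = 10,
                seed: int = 0) -> FittedLearner:
    """Fit one predictor, tuning its hyperparameters by k-fold CV."""
    fam = spec.family
    if fam in {"lasso", "ridge", "enet"}:
        alpha = {"lasso": 1.0, "ridge": 0.0}.get(fam, spec.params.get("alpha", 0.5))
        base = lambda_max(data, 1.0)
        grid = base * np.array(spec.params.get("lambda_fracs",
                                               (1.0, 0.3, 0.1, 0.03, 0.01)))
        if len(grid) > 1:
            cvs = [
                _cv_cindex(lambda d, lam=lam: fit_penalized_cox(d, alpha=alpha, lam=lam),
                           data, k, seed)
                for lam in grid
            ]
            lam = float(grid[int(np.nanargmax(cvs))])
        else:
            lam = float(grid[0])
        fit = fit_penalized_cox(data, alpha=alpha, lam=lam)
        return FittedLearner(spec.id, "linear",
                             _linear_payload(fit.beta_std, fit.center, fit.scale)
                             | {"lambda": lam, "alpha": alpha})
    if fam == "stepwise":
        cols, fit = stepwise_cox(data, direction=spec.params.get("direction", "both"))
        beta = np.zeros(data.p)
        beta[np.asarray(cols, dtype=int)] = fit.beta
        return FittedLearner(spec.id, "linear", _linear_payload(beta))
    if fam == "coxboost":
        grid = spec.params.get("step_grid", (25, 50, 100))
        steps = (cv_coxboost_steps(data, step_grid=grid, k=k, seed=seed)
                 if len(grid) > 1 else int(grid[0]))
        fit = fit_coxboost(data, n_steps=steps)
        return FittedLearner(spec.id, "linear",
                             _linear_payload(fit.beta, fit.center, fit.scale)
                             | {"n_steps": steps})
    if fam == "rsf":
        model = fit_rsf(data,
                        n_trees=spec.params.get("n_trees", 200),
                        mtry=spec.params.get("mtry"),
                        nodesize=spec.params.get("nodesize", 15),
                        seed=seed)
        return FittedLearner(spec.id, "rsf", model.to_dict())
    if fam == "cox":
        fit = fit_cox(data)
        return FittedLearner(spec.id, "linear", _linear_payload(fit.beta))
    raise ValueError(f"no fitting routine for family {fam!r}")


def select_features(spec: LearnerSpec, data: SurvivalData, k: int = 10,
                    seed: int = 0) -> list[int]:
    """Run a selector-role learner and return the selected column indices."""
    fam = spec.family
    if fam == "lasso":
        base = lambda_max(data, 1.0)
        grid = base * np.array(spec.params.get("lambda_fracs",
                                               (1.0, 0.3, 0.1, 0.03, 0.01)))
        cvs = [
            _cv_cindex(lambda d, lam=lam: fit_penalized_cox(d, alpha=1.0, lam=lam),
                       data, k, seed)
            for lam in grid
        ]
        lam = float(grid[int(np.nanargmax(cvs))])
        fit = fit_penalized_cox(data, alpha=1.0, lam=lam)
        return fit.selected.tolist()
    if fam == "stepwise":
        cols, _ = stepwise_cox(data, direction=spec.params.get("direction", "both"))
        return sorted(cols)
    if fam == "coxboost":
        grid = spec.params.get("step_grid", (25, 50, 100))
        steps = (cv_coxboost_steps(data, step_grid=grid, k=k, seed=seed)
                 if len(grid) > 1 else int(grid[0]))
        fit = fit_coxboost(data, n_steps=steps)
        return fit.selected.tolist()
    if fam == "rsf":
        model = fit_rsf(data,
                        n_trees=spec.params.get("n_trees", 200),
                        mtry=spec.params.get("mtry"),
                        nodesize=spec.params.get("nodesize", 15),
                        seed=seed)
        imp = variable_importance(model, data, seed=seed)
        return np.flatnonzero(imp > 0).tolist()
    raise ValueError(f"family {fam!r} has no selector routine")


# ---------------------------------------------------------------------------
# Cohort plumbing


def cohort_to_data(cohort, features) -> SurvivalData:
    """Extract a SurvivalData view of a cohort restricted to ``features``."""
    features = list(features)
    missing = [f for f in features if f not in cohort.expression.data.index]
    if missing:
        raise KeyError(f"cohort is missing signature feature(s): {missing[:10]}")
    X = cohort.expression.data.loc[features].to_numpy(dtype=float).T
    clin = cohort.clinical
    return SurvivalData(clin["time"].to_numpy(), clin["event"].to_numpy(), X,
                        feature_names=features)


def _standardize_to_training(X: np.ndarray, mode: str,
                             center: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Map covariates onto the training scale.

    ``training``: leave values as-is (the learner's internal training
    standardization applies).  ``per_cohort``: z-score within the cohort,
    then re-express on the training scale, which absorbs feature-wise
    additive batch shifts between platforms.
    """
    if mode == "training":
        return X
    if mode == "per_cohort":
        m = X.mean(axis=0)
        s = X.std(axis=0)
        s = np.where(s > 0, s, 1.0)
        return (X - m) / s * scale + center
    raise ValueError(f"unknown standardization mode {mode!r}")


# ---------------------------------------------------------------------------
# Running combinations


@dataclass
class ComboResult:
    combo: ComboSpec
    cindex: dict            # cohort name -> C-index (training included under "train")
    mean_validation: float
    n_features: int
    features: list[str]
    seed: int
    failed: bool = False
    reason: str | None = None


def run_combo(
    combo: ComboSpec,
    registry: dict[str, LearnerSpec],
    train,
    validations: dict,
    features,
    k: int = 10,
    seed: int = 0,
    standardize: str = "per_cohort",
) -> ComboResult:
    """Train one combination and evaluate C-index on every cohort.

    ``validations`` maps cohort names to SurvivalCohort objects.  The mean
    ranking metric covers validation cohorts only.
    """
    features = list(features)
    data = cohort_to_data(train, features)
    if data.n_events < k:
        raise ValueError("training cohort needs at least k events")
    center = data.covariates.mean(axis=0)
    scale = data.covariates.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)

    if combo.selector is not None:
        sel_spec = registry[combo.selector]
        cols = select_features(sel_spec, data, k=k, seed=seed)
        if len(cols) == 0:
            return ComboResult(combo, {}, np.nan, 0, [], seed, failed=True,
                               reason="selector returned no features")
        sub_features = [features[c] for c in cols]
    else:
        sub_features = features
    sub = cohort_to_data(train, sub_features)
    model = fit_learner(registry[combo.predictor], sub, k=k, seed=seed)

    sub_center = center[[features.index(f) for f in sub_features]]
    sub_scale = scale[[features.index(f) for f in sub_features]]
    cindex = {}
    risk_train = model.predict(sub.covariates)
    cindex["train"] = concordance_index(risk_train, sub)
    vals = []
    for name, cohort in validations.items():
        vdata = cohort_to_data(cohort, sub_features)
        Xv = _standardize_to_training(vdata.covariates, standardize,
                                      sub_center, sub_scale)
        ci = concordance_index(model.predict(Xv), vdata)
        cindex[name] = ci
        vals.append(ci)
    mean_val = float(np.mean(vals)) if vals else np.nan
    return ComboResult(combo, cindex, mean_val, len(sub_features),
                       sub_features, seed)


def select_best(results) -> ComboSpec:
    """Highest mean validation C-index; ties go to fewer features, then id."""
    ok = [r for r in results if not r.failed and np.isfinite(r.mean_validation)]
    if not ok:
        raise ValueError("all combinations failed")
    ranked = sorted(ok, key=lambda r: (-r.mean_validation, r.n_features, r.combo.id))
    return ranked[0].combo


def leaderboard(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"combo": r.combo.id, "mean_validation_cindex": r.mean_validation,
               "n_features": r.n_features, "failed": r.failed}
        row.update({f"cindex_{k}": v for k, v in r.cindex.items()})
        rows.append(row)
    df = pd.DataFrame(rows).set_index("combo")
    return df.sort_values("mean_validation_cindex", ascending=False)


# ---------------------------------------------------------------------------
# The final signature


@dataclass
class SignatureModel:
    """Selected lncRNAs + fitted predictor + training standardization + cutpoint."""

    features: list[str]
    predictor: FittedLearner
    center: np.ndarray
    scale: np.ndarray
    cutpoint: float
    provenance: dict = field(default_factory=dict)

    def score(self, cohort, restandardize: bool = False) -> pd.Series:
        """Risk score per sample; higher scores mean worse expected outcome."""
        data = cohort_to_data(cohort, self.features)
        X = _standardize_to_training(
            data.covariates, "per_cohort" if restandardize else "training",
            self.center, self.scale)
        return pd.Series(self.predictor.predict(X),
                         index=cohort.expression.sample_ids, name="risk_score")

    def to_json(self, path=None) -> str:
        blob = json.dumps({
            "features": self.features,
            "predictor": self.predictor.to_dict(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "cutpoint": self.cutpoint,
            "provenance": self.provenance,
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob

    @classmethod
    def from_json(cls, blob_or_path) -> "SignatureModel":
        try:
            d = json.loads(blob_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(blob_or_path) as fh:
                d = json.load(fh)
        return cls(features=d["features"],
                   predictor=FittedLearner.from_dict(d["predictor"]),
                   center=np.asarray(d["center"], dtype=float),
                   scale=np.asarray(d["scale"], dtype=float),
                   cutpoint=float(d["cutpoint"]),
                   provenance=d.get("provenance", {}))


def build_signature(
    train,
    registry: dict[str, LearnerSpec],
    features,
    selector: str | None,
    predictor: str,
    k: int = 10,
    seed: int = 0,
    minprop: float = 0.1,
) -> SignatureModel:
    """Fit the final signature on the training cohort.

    The selector (if any) picks the signature lncRNAs on the full training
    data, the predictor is refit on that subset, and the stratification
    cutpoint is the maximally selected log-rank cutpoint of the training
    risk scores.
    """
    features = list(features)
    data = cohort_to_data(train, features)
    if selector is not None:
        cols = select_features(registry[selector], data, k=k, seed=seed)
        if not cols:
            raise ValueError("selector returned no features")
        sig_features = [features[c] for c in cols]
    else:
        sig_features = features
    sub = cohort_to_data(train, sig_features)
    model = fit_learner(registry[predictor], sub, k=k, seed=seed)
    center = sub.covariates.mean(axis=0)
    scale = sub.covariates.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    scores = model.predict(sub.covariates)
    cut = optimal_cutpoint(scores, sub.time, sub.event, minprop=minprop)
    return SignatureModel(
        features=sig_features, predictor=model, center=center, scale=scale,
        cutpoint=float(cut),
        provenance={"selector": selector, "predictor": predictor, "seed": seed},
    )


def score_cohort(signature: SignatureModel, cohort,
                 restandardize: bool = False) -> pd.Series:
    return signature.score(cohort, restandardize=restandardize)


# ---------------------------------------------------------------------------
# Stratification and response association


def optimal_cutpoint(scores, time, event, minprop: float = 0.1) -> float:
    """Maximally selected log-rank cutpoint.

    Candidates are midpoints of consecutive distinct scores keeping at least
    ``minprop`` of the samples on each side; the returned cutpoint maximizes
    the absolute standardized two-group log-rank statistic, preferring the
    lower cutpoint on ties.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if np.all(scores == scores[0]):
        raise ValueError("all scores equal: no cutpoint exists")
    min_side = max(1, int(np.ceil(minprop * n)))
    data = SurvivalData(np.asarray(time, dtype=float), np.asarray(event),
                        np.zeros((n, 0)))
    lr = logrank_scores(data)
    if lr.var <= 0:
        raise ValueError("log-rank scores have zero variance")
    order = np.argsort(scores, kind="mergesort")
    xs = scores[order]
    prefix = np.cumsum(lr.a[order])
    n1 = np.arange(1, n)
    valid = (xs[:-1] < xs[1:]) & (n1 >= min_side) & (n - n1 >= min_side)
    if not valid.any():
        raise ValueError("no admissible cutpoint under minprop")
    s = np.where(valid,
                 (prefix[:-1] - n1 * lr.mean)
                 / np.sqrt(n1 * (1 - n1 / n) * lr.var), 0.0)
    best = int(np.argmax(np.where(valid, np.abs(s), -np.inf)))
    return float(0.5 * (xs[best] + xs[best + 1]))


def stratify_and_test(scores, cutpoint: float, time, event) -> dict:
    """Split at the cutpoint (high = score > cutpoint), KM per group, log-rank."""
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if not scores.min() < cutpoint < scores.max():
        raise ValueError("cutpoint must lie strictly inside the score range")
    high = scores > cutpoint
    if high.all() or not high.any():
        raise ValueError("stratification produced an empty group")
    chi2, p = logrank_test(time, event, high.astype(int))
    return {
        "groups": np.where(high, "high", "low"),
        "km_high": km_estimate(time[high], event[high]),
        "km_low": km_estimate(time[~high], event[~high]),
        "chi2": chi2,
        "p": p,
    }


def response_association(scores, response, cutpoint: float | None = None) -> dict:
    """Wilcoxon rank-sum of scores by immunotherapy response + contingency.

    ``response`` is a binary vector (1 = responder).  The 2x2 contingency
    table crosses score group (above/below ``cutpoint``; median when not
    given) with response.
    """
    scores = np.asarray(scores, dtype=float)
    response = np.asarray(response).astype(int)
    if set(np.unique(response)) != {0, 1}:
        raise ValueError("both response labels must be present")
    u, p = stats.mannwhitneyu(scores[response == 1], scores[response == 0],
                              alternative="two-sided")
    if cutpoint is None:
        cutpoint = float(np.median(scores))
    high = scores > cutpoint
    table = np.array([
        [np.sum(high & (response == 1)), np.sum(high & (response == 0))],
        [np.sum(~high & (response == 1)), np.sum(~high & (response == 0))],
    ])
    return {"statistic": float(u), "p": float(p), "cutpoint": float(cutpoint),
            "contingency": table}


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping, for provenance fields."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
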