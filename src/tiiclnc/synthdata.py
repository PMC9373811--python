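"""Synthetic purified-immune-cell, tumor-cell-line and bulk survival cohorts.

The generator plants a known answer for every stage of the signature
pipeline.  lncRNAs fall into four classes:

``general_immune``
    highly and uniformly expressed across all immune cell types, depleted in
    tumor lines — the class the screen is designed to find.  A declared
    subset carries nonzero Cox log-hazard coefficients in the bulk cohorts.
``cell_type_specific``
    high in exactly one immune cell type (removed by the specificity index).
``tumor_enriched``
    low in immune lines, high in tumor lines (removed by the differential
    filter).
``background``
    low everywhere.

Bulk tumors are infiltration-weighted mixtures of the immune and tumor
expression prototypes on the log2 scale, plus noise and a per-cohort batch
shift.  Survival times follow an exponential proportional-hazards model
h0 * exp(sum_g beta_g * z_g) on the standardized bulk expression of the
planted lncRNAs; censoring is independent exponential with its rate solved
numerically to hit the configured censoring fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exprprep import ExpressionMatrix

CLASSES = ("general_immune", "cell_type_specific", "tumor_enriched", "background")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts (all defaults documented).

    Expression values are on the log2 scale.  ``sd_general`` is deliberately
    tighter than ``sd_expr``: "generally expressed across immune cell types"
    is a statement about cross-type stability, and the specificity index
    (computed on linear intensities) only stays below 0.2 when the per-type
    means vary little.
    """

    n_cell_types: int = 19
    lines_per_type: int = 5
    n_lnc: int = 2000
    n_tumor_lines: int = 10
    n_patients: int = 500
    n_cohorts: int = 3
    frac_general: float = 0.02
    frac_specific: float = 0.10
    frac_tumor: float = 0.05
    mean_high: float = 7.0       # log2 mean of an expressed lncRNA
    mean_low: float = 2.0        # log2 mean of an unexpressed lncRNA
    sd_expr: float = 1.0         # replicate noise, log2 units
    sd_general: float = 0.2      # replicate noise of general-immune lncRNAs
    tumor_shift: float = 4.0     # log2 depletion of general lncs in tumor lines
    n_prognostic: int = 16       # general-immune lncRNAs with planted betas
    beta_magnitude: float = 0.7  # |log-hazard| per SD of expression
    sd_bulk: float = 1.5         # residual noise in bulk mixtures
    baseline_hazard: float = 0.02  # events per month
    censoring_rate: float = 0.3    # target censored fraction
    batch_shift_sd: float = 0.3    # per-cohort per-lncRNA offset (cohort > 0)
    infiltration_a: float = 2.0    # Beta(a, b) immune fraction
    infiltration_b: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        fr = self.frac_general + self.frac_specific + self.frac_tumor
        if not (0 <= fr <= 1):
            raise ConfigError("class fractions must sum to at most 1")
        for name in ("n_cell_types", "lines_per_type", "n_lnc", "n_tumor_lines",
                     "n_patients", "n_cohorts"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigError("censoring_rate must lie in [0, 1)")
        if self.n_prognostic > int(self.frac_general * self.n_lnc):
            raise ConfigError("n_prognostic exceeds the general_immune class size")
        if self.seed is None:
            raise ConfigError("seed is mandatory")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Planted truth: class labels, specific types, betas, infiltration."""

    lnc_ids: list[str]
    lnc_class: np.ndarray        # one of CLASSES per lncRNA
    specific_type: np.ndarray    # cell-type index, -1 if not type-specific
    planted_beta: np.ndarray     # Cox log-hazard per SD; 0 if non-prognostic
    infiltration: dict = field(default_factory=dict)  # cohort_index -> fractions

    def __post_init__(self) -> None:
        if not set(np.unique(self.lnc_class)) <= set(CLASSES):
            raise ValueError("unknown lncRNA class label")
        nonzero = np.flatnonzero(self.planted_beta)
        if len(nonzero) and not np.all(self.lnc_class[nonzero] == "general_immune"):
            raise ValueError("planted betas must sit on general_immune lncRNAs")

    @property
    def prognostic_ids(self) -> list[str]:
        return [self.lnc_ids[i] for i in np.flatnonzero(self.planted_beta)]

    def ids_of_class(self, cls: str) -> list[str]:
        return [self.lnc_ids[i] for i in np.flatnonzero(self.lnc_class == cls)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lnc_id": self.lnc_ids,
            "lnc_class": self.lnc_class,
            "specific_type": self.specific_type,
            "planted_beta": self.planted_beta,
        }).set_index("lnc_id")


@dataclass
class SurvivalCohort:
    """Bulk expression joined to per-sample survival outcomes."""

    expression: ExpressionMatrix
    clinical: pd.DataFrame  # index sample_id; columns time, event, ...

    def __post_init__(self) -> None:
        if not self.expression.sample_ids.equals(self.clinical.index):
            raise ValueError("expression samples and clinical rows must match")
        if (self.clinical["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not self.clinical["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")


def _class_counts(config: SimulationConfig) -> dict[str, int]:
    n = config.n_lnc
    counts = {
        "general_immune": int(np.floor(config.frac_general * n)),
        "cell_type_specific": int(np.floor(config.frac_specific * n)),
        "tumor_enriched": int(np.floor(config.frac_tumor * n)),
    }
    counts["background"] = n - sum(counts.values())
    return counts


def _immune_type_means(config: SimulationConfig, gt: GroundTruth) -> np.ndarray:
    """(n_lnc, n_cell_types) log2 mean of each lncRNA in each immune type."""
    means = np.full((config.n_lnc, config.n_cell_types), config.mean_low)
    means[gt.lnc_class == "general_immune", :] = config.mean_high
    for i in np.flatnonzero(gt.lnc_class == "cell_type_specific"):
        means[i, gt.specific_type[i]] = config.mean_high
    return means


def generate_immune_panel(config: SimulationConfig):
    """Purified immune cell lines: (ExpressionMatrix, annotation, GroundTruth).

    Columns are ``lines_per_type * n_cell_types`` cell lines; the annotation
    Series maps each line to its immune cell type.
    """
    config.validate()
    counts = _class_counts(config)
    classes = np.concatenate([
        np.repeat(cls, counts[cls]) for cls in CLASSES
    ]).astype(object)
    specific_type = np.full(config.n_lnc, -1)
    spec_idx = np.flatnonzero(classes == "cell_type_specific")
    specific_type[spec_idx] = np.arange(len(spec_idx)) % config.n_cell_types
    beta = np.zeros(config.n_lnc)
    prog = np.flatnonzero(classes == "general_immune")[: config.n_prognostic]
    half = len(prog) // 2
    beta[prog[:half]] = config.beta_magnitude
    beta[prog[half:]] = -config.beta_magnitude

    lnc_ids = [f"LNC{i:05d}" for i in range(config.n_lnc)]
    gt = GroundTruth(lnc_ids=lnc_ids, lnc_class=np.asarray(classes),
                     specific_type=specific_type, planted_beta=beta)

    means = _immune_type_means(config, gt)
    sd = np.where(gt.lnc_class == "general_immune", config.sd_general, config.sd_expr)
    rng = config._rng(0)
    n_lines = config.n_cell_types * config.lines_per_type
    type_of_line = np.repeat(np.arange(config.n_cell_types), config.lines_per_type)
    noise = rng.normal(0.0, 1.0, size=(config.n_lnc, n_lines))
    values = means[:, type_of_line] + sd[:, None] * noise
    line_ids = [
        f"IMM_T{t:02d}_L{l}" for t in range(config.n_cell_types)
        for l in range(config.lines_per_type)
    ]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=lnc_ids, columns=line_ids), "log2")
    annotation = pd.Series(
        [f"type_{t:02d}" for t in type_of_line], index=line_ids, name="cell_type")
    return matrix, annotation, gt


def tumor_line_means(config: SimulationConfig, gt: GroundTruth) -> np.ndarray:
    """log2 mean of each lncRNA in tumor cell lines."""
    means = np.full(config.n_lnc, config.mean_low)
    means[gt.lnc_class == "general_immune"] = config.mean_high - config.tumor_shift
    means[gt.lnc_class == "tumor_enriched"] = config.mean_low + config.tumor_shift
    return means


def generate_tumor_lines(config: SimulationConfig, gt: GroundTruth) -> ExpressionMatrix:
    """Tumor cell lines: general-immune lncRNAs depleted, tumor class enriched."""
    config.validate()
    if len(gt.lnc_ids) != config.n_lnc:
        raise ValueError("ground truth does not match config lncRNA universe")
    rng = config._rng(1)
    means = tumor_line_means(config, gt)
    values = means[:, None] + rng.normal(0.0, config.sd_expr,
                                         size=(config.n_lnc, config.n_tumor_lines))
    cols = [f"TUM_L{l:02d}" for l in range(config.n_tumor_lines)]
    return ExpressionMatrix(pd.DataFrame(values, index=gt.lnc_ids, columns=cols), "log2")


def _solve_censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean(c / (c + h_i)) = target."""
    if target <= 0:
        return 0.0

    def frac(c: float) -> float:
        return float(np.mean(c / (c + hazards)))

    lo, hi = 1e-12, float(hazards.max())
    while frac(hi) < target:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_bulk_cohort(
    config: SimulationConfig, gt: GroundTruth, cohort_index: int
) -> SurvivalCohort:
    """One bulk cohort: mixture expression plus proportional-hazards survival.

    Cohort 0 is the training cohort (no batch shift); cohorts >= 1 receive an
    additive per-lncRNA batch offset drawn once per cohort.
    """
    config.validate()
    if not 0 <= cohort_index < config.n_cohorts:
        raise ValueError(f"cohort_index must lie in [0, {config.n_cohorts})")
    rng = config._rng(100 + cohort_index)
    n = config.n_patients

    immune_proto = _immune_type_means(config, gt).mean(axis=1)
    tumor_proto = tumor_line_means(config, gt)
    infiltration = rng.beta(config.infiltration_a, config.infiltration_b, size=n)
    batch = np.zeros(config.n_lnc)
    if cohort_index > 0 and config.batch_shift_sd > 0:
        batch = rng.normal(0.0, config.batch_shift_sd, size=config.n_lnc)
    noise = rng.normal(0.0, config.sd_bulk, size=(config.n_lnc, n))
    values = (
        immune_proto[:, None] * infiltration[None, :]
        + tumor_proto[:, None] * (1.0 - infiltration[None, :])
        + batch[:, None]
        + noise
    )

    prog = np.flatnonzero(gt.planted_beta)
    if len(prog):
        expr = values[prog, :]
        z = (expr - expr.mean(axis=1, keepdims=True)) / expr.std(axis=1, keepdims=True)
        lp = gt.planted_beta[prog] @ z
    else:
        lp = np.zeros(n)
    hazards = config.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        c_rate = _solve_censoring_rate(hazards, config.censoring_rate)
        censor_time = rng.exponential(1.0 / c_rate, size=n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-8)

    samples = [f"C{cohort_index}_P{i:04d}" for i in range(n)]
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=gt.lnc_ids, columns=samples), "log2")
    clinical = pd.DataFrame(
        {"time": time, "event": event, "infiltration": infiltration,
         "true_linear_predictor": lp},
        index=pd.Index(samples, name="sample_id"),
    )
    gt.infiltration[cohort_index] = infiltration
    return SurvivalCohort(expression=expression, clinical=clinical)


def generate_study(config: SimulationConfig):
    """Convenience: immune panel, tumor lines and all bulk cohorts at once."""
    immune, annotation, gt = generate_immune_panel(config)
    tumor = generate_tumor_lines(config, gt)
    cohorts = [generate_bulk_cohort(config, gt, i) for i in range(config.n_cohorts)]
    return immune, annotation, tumor, cohorts, gt
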