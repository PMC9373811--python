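"""The four-stage TIIClncRNA screen.

1. ``top_expressed_candidates`` — the top 15% expressed lncRNAs in each
   purified immune cell line, aggregated across lines.
2. ``tsi`` + ``select_general_ilncs`` — the tissue/cell-type specificity
   index TSI = sum_i (1 - x_i) / (N - 1), where x_i is the per-type mean
   expression normalized by its maximum over the N immune cell types;
   candidates with TSI < 0.2 are "general" immune lncRNAs (ilncRNAs).
3. ``differential_filter`` — ilncRNAs significantly up in immune cell lines
   and down in tumor cell lines (Welch's t, BH-adjusted) are TIIClncRNAs.
4. ``univariate_cox_screen`` — TIIClncRNAs with prognostic signal in a bulk
   cohort (single-covariate Cox, Wald p below alpha).

Each stage records its statistics in a :class:`ScreenTrace`, whose stage
outputs are nested by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exprprep import ExpressionMatrix, unlog2
from .survlearn import SurvivalData, fit_cox


@dataclass
class TsiTable:
    """Per-lncRNA specificity index and the max-normalized profile behind it."""

    table: pd.DataFrame      # index lnc_id; column "tsi" (NaN if undefined)
    x_profile: pd.DataFrame  # index lnc_id; one column per cell type
    n_types: int

    @property
    def tsi(self) -> pd.Series:
        return self.table["tsi"]


@dataclass
class ScreenStage:
    name: str
    n_in: int
    n_out: int
    selected: list[str]
    stats: pd.DataFrame | None = None


@dataclass
class ScreenTrace:
    """Audit trail of the screen; verifies the stage-nesting invariant."""

    stages: list[ScreenStage] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def add(self, stage: ScreenStage) -> None:
        if self.stages:
            prev = set(self.stages[-1].selected)
            if not set(stage.selected) <= prev:
                raise ValueError(
                    f"stage {stage.name!r} output is not nested in its input")
        self.stages.append(stage)

    @property
    def final(self) -> list[str]:
        return self.stages[-1].selected if self.stages else []

    def summary(self) -> dict:
        return {
            "params": self.params,
            "stages": [
                {"name": s.name, "n_in": s.n_in, "n_out": s.n_out}
                for s in self.stages
            ],
        }

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in self.stages:
            if s.stats is not None:
                s.stats.to_csv(outdir / f"stage_{s.name}.tsv", sep="\t")
            pd.Series(s.selected, name="lnc_id").to_csv(
                outdir / f"stage_{s.name}_selected.tsv", sep="\t", index=False)
        with open(outdir / "screen_summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, default=str)


def top_expressed_candidates(
    immune_matrix: ExpressionMatrix,
    fraction: float = 0.15,
    aggregation: str = "union",
) -> tuple[list[str], pd.Series]:
    """Top-``fraction`` expressed lncRNAs per immune cell line, aggregated.

    Each line (column) contributes its ceil(fraction * n_lnc) most expressed
    lncRNAs (ties broken by feature order).  Aggregation across lines is the
    union by default; ``aggregation="intersection"`` requires a lncRNA to be
    top-ranked in every line.  Returns the sorted candidate list and the
    per-line marked counts.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if immune_matrix.data.empty:
        raise ValueError("empty expression matrix")
    if aggregation not in {"union", "intersection"}:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    n_lnc = immune_matrix.data.shape[0]
    k = int(np.ceil(fraction * n_lnc))
    marked: set[str] | None = None
    counts = {}
    for col in immune_matrix.sample_ids:
        vals = immune_matrix.data[col].to_numpy()
        order = np.lexsort((np.arange(n_lnc), -vals))  # desc value, stable index
        top = set(immune_matrix.feature_ids[order[:k]])
        counts[col] = len(top)
        if marked is None:
            marked = top
        elif aggregation == "union":
            marked |= top
        else:
            marked &= top
    return sorted(marked), pd.Series(counts, name="n_marked")


def tsi(immune_matrix: ExpressionMatrix, annotation: pd.Series) -> TsiTable:
    """Specificity index over immune cell types.

    Replicate lines are averaged within each cell type on the *linear*
    intensity scale (a log2 matrix is un-logged first), the per-type profile
    is normalized by its maximum, and TSI = sum_i (1 - x_i) / (N - 1).
    TSI is 0 for a lncRNA expressed identically in every type and 1 for one
    expressed in a single type.  All-zero lncRNAs get NaN with a warning.
    """
    annotation = annotation.reindex(immune_matrix.sample_ids)
    if annotation.isna().any():
        missing = annotation.index[annotation.isna()].tolist()
        raise ValueError(f"annotation missing for sample(s): {missing[:5]}")
    n_types = annotation.nunique()
    if n_types < 2:
        raise ValueError("need at least two cell types")
    linear = unlog2(immune_matrix) if immune_matrix.scale == "log2" else immune_matrix
    profile = linear.data.T.groupby(annotation).mean().T  # lnc x type
    maxima = profile.max(axis=1)
    zero = maxima <= 0
    if zero.any():
        warnings.warn(f"TSI undefined for {int(zero.sum())} all-zero lncRNA(s)")
    with np.errstate(divide="ignore", invalid="ignore"):
        x = profile.div(maxima, axis=0)
    tsi_values = (1.0 - x).sum(axis=1) / (n_types - 1)
    tsi_values[zero] = np.nan
    x[zero] = np.nan
    return TsiTable(table=pd.DataFrame({"tsi": tsi_values}),
                    x_profile=x, n_types=int(n_types))


def select_general_ilncs(
    tsi_table: TsiTable, candidates, threshold: float = 0.2
) -> list[str]:
    """Candidates with TSI strictly below the generality threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    values = tsi_table.tsi
    out = [c for c in candidates
           if c in values.index and np.isfinite(values[c]) and values[c] < threshold]
    return sorted(out)


def differential_filter(
    immune_matrix: ExpressionMatrix,
    tumor_matrix: ExpressionMatrix,
    ilncs,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """ilncRNAs up in immune lines and down in tumor lines.

    Welch's two-sample t-test per lncRNA on the log2 matrices with
    Benjamini-Hochberg control at ``alpha``; retained lncRNAs must also have
    mean(immune) > mean(tumor).  Returns the retained list and a table of
    (statistic, raw p, BH-adjusted p, log2 fold change).
    """
    ilncs = list(ilncs)
    if immune_matrix.scale != "log2" or tumor_matrix.scale != "log2":
        raise ValueError("differential_filter expects log2 matrices")
    if immune_matrix.data.shape[1] < 2 or tumor_matrix.data.shape[1] < 2:
        raise ValueError("each group needs at least two samples")
    if not ilncs:
        return [], pd.DataFrame(columns=["statistic", "p", "p_adj", "lfc"])
    imm = immune_matrix.data.loc[ilncs].to_numpy()
    tum = tumor_matrix.data.loc[ilncs].to_numpy()
    stat, p = stats.ttest_ind(imm, tum, axis=1, equal_var=False)
    p_adj = stats.false_discovery_control(p, method="bh")
    lfc = imm.mean(axis=1) - tum.mean(axis=1)
    table = pd.DataFrame(
        {"statistic": stat, "p": p, "p_adj": p_adj, "lfc": lfc},
        index=pd.Index(ilncs, name="lnc_id"))
    keep = table[(table["p_adj"] < alpha) & (table["lfc"] > 0)]
    return sorted(keep.index), table


def univariate_cox_screen(
    cohort, tiiclncs, alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Single-covariate Cox fits per lncRNA; retain Wald p < alpha.

    Expression is z-scored per lncRNA before fitting, so hazard ratios are
    per SD of expression.  Zero-variance lncRNAs are skipped with a warning.
    """
    tiiclncs = list(tiiclncs)
    clin = cohort.clinical
    if int(clin["event"].sum()) < 2:
        raise ValueError("cohort has fewer than two events")
    rows = []
    kept = []
    for lnc in tiiclncs:
        x = cohort.expression.data.loc[lnc].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            warnings.warn(f"zero-variance lncRNA {lnc!r} skipped in Cox screen")
            continue
        z = (x - x.mean()) / sd
        data = SurvivalData(clin["time"].to_numpy(), clin["event"].to_numpy(),
                            z[:, None])
        fit = fit_cox(data)
        hr = float(fit.hazard_ratios[0])
        ci = fit.conf_int()[0]
        pval = float(fit.wald_p[0])
        rows.append({"lnc_id": lnc, "hr": hr, "ci_low": ci[0], "ci_high": ci[1],
                     "wald_p": pval,
                     "direction": "hazardous" if hr > 1 else "protective",
                     "converged": fit.converged})
        if fit.converged and pval < alpha:
            kept.append(lnc)
    table = pd.DataFrame(rows).set_index("lnc_id") if rows else pd.DataFrame(
        columns=["hr", "ci_low", "ci_high", "wald_p", "direction", "converged"])
    return sorted(kept), table


def run_screen(
    immune_matrix: ExpressionMatrix,
    annotation: pd.Series,
    tumor_matrix: ExpressionMatrix,
    cohort,
    fraction: float = 0.15,
    tsi_threshold: float = 0.2,
    diff_alpha: float = 0.05,
    cox_alpha: float = 0.05,
    aggregation: str = "union",
) -> ScreenTrace:
    """Run all four stages and return the populated trace."""
    trace = ScreenTrace(params={
        "fraction": fraction, "tsi_threshold": tsi_threshold,
        "diff_alpha": diff_alpha, "cox_alpha": cox_alpha,
        "aggregation": aggregation,
    })
    n_all = immune_matrix.data.shape[0]
    candidates, counts = top_expressed_candidates(immune_matrix, fraction, aggregation)
    trace.add(ScreenStage("top_expressed", n_all, len(candidates), candidates,
                          counts.to_frame()))
    tsi_table = tsi(immune_matrix, annotation)
    ilncs = select_general_ilncs(tsi_table, candidates, tsi_threshold)
    trace.add(ScreenStage("tsi_general", len(candidates), len(ilncs), ilncs,
                          tsi_table.table.loc[candidates]))
    tiic, diff_table = differential_filter(immune_matrix, tumor_matrix, ilncs, diff_alpha)
    trace.add(ScreenStage("differential", len(ilncs), len(tiic), tiic, diff_table))
    prognostic, cox_table = univariate_cox_screen(cohort, tiic, cox_alpha)
    trace.add(ScreenStage("univariate_cox", len(tiic), len(prognostic), prognostic,
                          cox_table))
    return trace
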