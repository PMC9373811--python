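"""Expression-matrix ingestion, unit conversion, normalization and alignment.

The pipeline works on lncRNA-by-sample matrices.  Matrices carry an explicit
``scale`` flag (``linear_fpkm``, ``linear_tpm`` or ``log2``) so that unit
conversions cannot silently be applied twice.  All readers reject missing
values: the downstream statistics assume complete matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALES = ("linear_fpkm", "linear_tpm", "log2")


class ScaleError(ValueError):
    """Raised when an operation is applied to a matrix on the wrong scale."""


@dataclass
class ExpressionMatrix:
    """A features-by-samples expression matrix with an explicit scale.

    Parameters
    ----------
    data:
        DataFrame with lncRNA identifiers as the index and sample identifiers
        as columns.  Values must be numeric and complete (no NaN).
    scale:
        One of ``linear_fpkm``, ``linear_tpm``, ``log2``.  Linear scales must
        be nonnegative.
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ScaleError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("expression matrix contains missing values; not supported")
        if self.scale.startswith("linear") and (values < 0).any():
            raise ValueError(f"negative values in a {self.scale} matrix")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.scale)


@dataclass
class ProbeMap:
    """Many-to-one mapping from probe ids to feature (lncRNA) ids."""

    mapping: pd.Series  # index: probe_id, values: feature_id

    def __post_init__(self) -> None:
        if len(self.mapping) == 0:
            raise ValueError("empty probe map")
        if (self.mapping.astype(str).str.len() == 0).any():
            raise ValueError("probe map contains empty feature ids")


def fpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM by per-sample renormalization to one million.

    TPM_g = FPKM_g / sum_g FPKM_g * 1e6, per sample; every output column sums
    to 1e6 exactly (up to float rounding).
    """
    if matrix.scale != "linear_fpkm":
        raise ScaleError(f"fpkm_to_tpm expects linear_fpkm input, got {matrix.scale}")
    colsums = matrix.data.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero) > 0:
        raise ValueError(f"all-zero expression column(s): {zero.index.tolist()}")
    tpm = matrix.data.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(tpm, "linear_tpm")


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount), linear input only."""
    if matrix.scale == "log2":
        raise ScaleError("matrix is already on log2 scale")
    if (matrix.values < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    out = np.log2(matrix.data + pseudocount)
    return ExpressionMatrix(out, "log2")


def unlog2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Invert the log2 scale (2**value); used where linear intensities are needed."""
    if matrix.scale != "log2":
        raise ScaleError("unlog2 expects a log2 matrix")
    return ExpressionMatrix(np.exp2(matrix.data), "linear_tpm")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of row-wise sorted means.

    Each column is replaced by the mean-of-sorted-columns reference at its own
    ranks; ties within a column receive the average of the reference values
    over the tied ranks.  A single-sample matrix is returned unchanged with a
    warning.
    """
    if matrix.data.shape[1] < 2:
        warnings.warn("quantile_normalize on a single sample is the identity")
        return matrix.copy()
    x = matrix.values
    sorted_cols = np.sort(x, axis=0)
    reference = sorted_cols.mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(col))
        normalized = reference[ranks]
        # average the reference over tied input values
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < len(col):
            sums = np.bincount(inv, weights=normalized)
            counts = np.bincount(inv)
            normalized = (sums / counts)[inv]
        out[:, j] = normalized
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.feature_ids, columns=matrix.sample_ids),
        matrix.scale,
    )


def collapse_probes(matrix: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per feature id.

    When several probes map to the same lncRNA, the probe with the highest mean
    expression is kept (a common deterministic convention).  Rows absent from
    the map are dropped; the number dropped is reported in a warning.
    """
    mapped = matrix.data.index.intersection(probe_map.mapping.index)
    n_dropped = matrix.data.shape[0] - len(mapped)
    if n_dropped:
        warnings.warn(f"collapse_probes: dropping {n_dropped} unmapped probe row(s)")
    if len(mapped) == 0:
        raise ValueError("no matrix rows present in the probe map")
    sub = matrix.data.loc[mapped]
    features = probe_map.mapping.loc[mapped]
    means = sub.mean(axis=1)
    # stable winner per feature: highest mean, ties to the first probe in row order
    best = (
        pd.DataFrame({"feature": features.to_numpy(), "mean": means.to_numpy()}, index=sub.index)
        .reset_index(names="probe")
        .sort_values(["feature", "mean"], ascending=[True, False], kind="mergesort")
        .drop_duplicates("feature")
    )
    out = sub.loc[best["probe"]]
    out.index = pd.Index(best["feature"].to_numpy(), name=matrix.data.index.name)
    return ExpressionMatrix(out, matrix.scale)


def intersect_features(*matrices: ExpressionMatrix) -> list[ExpressionMatrix]:
    """Restrict all matrices to their shared, identically ordered feature set.

    The output feature order is the sorted intersection, so the result is
    invariant to the order in which matrices are supplied.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    shared = matrices[0].data.index
    for m in matrices[1:]:
        shared = shared.intersection(m.data.index)
    if len(shared) == 0:
        raise ValueError("feature intersection is empty")
    shared = shared.sort_values()
    return [ExpressionMatrix(m.data.loc[shared], m.scale) for m in matrices]


# ---------------------------------------------------------------------------
# TSV dialect: one "#scale=" comment line, then a header of sample ids with
# the first column holding feature ids.

def write_matrix_tsv(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#scale={matrix.scale}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="feature_id")


def read_matrix_tsv(path) -> ExpressionMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#scale="):
            raise ValueError(f"{path}: missing '#scale=' header line")
        scale = first.split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index.name = None
    return ExpressionMatrix(df, scale)
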