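"""Bench-side readouts: the IHC H-score and signature-marker correlation.

The H-score is the semi-quantitative immunohistochemistry score: staining
intensity (0 negative, 1 weak, 2 moderate, 3 strong) times stained-cell
quantity category (0: <10%, 1: 10-25%, 2: 25-50%, 3: 50-75%, 4: >75%),
ranging 0 to 12.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

INTENSITY_LEVELS = (0, 1, 2, 3)
QUANTITY_LEVELS = (0, 1, 2, 3, 4)


def h_score(intensity: int, quantity: int) -> int:
    """intensity x quantity, on the enumerated IHC scales; integer in [0, 12]."""
    if intensity not in INTENSITY_LEVELS:
        raise ValueError(f"intensity must be one of {INTENSITY_LEVELS}, got {intensity!r}")
    if quantity not in QUANTITY_LEVELS:
        raise ValueError(f"quantity must be one of {QUANTITY_LEVELS}, got {quantity!r}")
    return int(intensity) * int(quantity)


def h_score_table(records) -> pd.DataFrame:
    """Tabulate (sample, marker, intensity, quantity) records with H-scores."""
    df = pd.DataFrame(records, columns=["sample", "marker", "intensity", "quantity"])
    df["h_score"] = [h_score(i, q) for i, q in zip(df["intensity"], df["quantity"])]
    return df


def marker_correlation(scores, marker_values) -> tuple[float, float]:
    """Spearman correlation between signature scores and an immune marker.

    Rank-based by design: the signature score and IHC/expression markers live
    on unrelated scales.  Returns (rho, two-sided p).
    """
    scores = np.asarray(scores, dtype=float)
    marker_values = np.asarray(marker_values, dtype=float)
    if scores.shape != marker_values.shape:
        raise ValueError("scores and marker values must be paired")
    if len(scores) < 3:
        raise ValueError("need at least three pairs")
    if np.all(scores == scores[0]) or np.all(marker_values == marker_values[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(scores, marker_values)
    return float(rho), float(p)
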