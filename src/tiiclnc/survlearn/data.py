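"""Right-censored survival data container used by every learner."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SurvivalData:
    """Times, event indicators and a numeric covariate matrix.

    ``time`` must be strictly positive; ``event`` is 1 for an observed death
    and 0 for censoring.  ``covariates`` is an (n, p) array; learners that
    need standardization handle it themselves.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray
    feature_names: list[str] | None = None
    time_unit: str = "months"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.covariates is None:
            self.covariates = np.empty((len(self.time), 0))
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != len(self.time) and self.covariates.shape[1] == len(self.time):
            self.covariates = self.covariates.T
        if np.any(self.time <= 0):
            raise ValueError("survival times must be strictly positive")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicators must be 0 or 1")
        self.event = self.event.astype(int)
        if np.isnan(self.covariates).any():
            raise ValueError("covariates contain missing values")
        if self.covariates.shape[0] != len(self.time):
            raise ValueError("covariate rows must match number of subjects")
        if self.feature_names is not None and len(self.feature_names) != self.covariates.shape[1]:
            raise ValueError("feature_names length mismatch")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalData":
        idx = np.asarray(idx)
        return SurvivalData(
            self.time[idx], self.event[idx], self.covariates[idx],
            self.feature_names, self.time_unit,
        )

    def select_features(self, cols) -> "SurvivalData":
        cols = np.asarray(cols)
        names = None
        if self.feature_names is not None:
            names = [self.feature_names[int(c)] for c in cols]
        return SurvivalData(self.time, self.event, self.covariates[:, cols], names, self.time_unit)
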