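"""Inter-operator reliability: intraclass correlation, ICC(2,1).

Two operators extract the same features from the same plants; agreement is
quantified with the two-way random-effects, absolute-agreement,
single-measure intraclass correlation

    ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

where MS_R, MS_C and MS_E are the subject, rater and residual mean squares
of the two-way ANOVA of the n x k ratings matrix.  The absolute-agreement
form penalizes systematic per-rater offsets, unlike the consistency form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["RatingsMatrix", "ICCResult", "icc_a1"]


@dataclass
class RatingsMatrix:
    """n_subjects x k_raters matrix of one feature's values."""

    values: np.ndarray
    feature_name: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("ratings must be a matrix with >= 2 subjects and >= 2 raters")
        if not np.all(np.isfinite(v)):
            raise ValueError("ratings matrix must have no missing cells")
        self.values = v

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_raters(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model: str
    ms_rows: float
    ms_cols: float
    ms_error: float


def icc_a1(ratings: RatingsMatrix) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measure ICC.

    Degenerate all-equal data (zero total variance) returns 1.0 with a
    warning: the raters agree trivially.
    """
    x = ratings.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    ss_total = np.sum((x - grand) ** 2)
    if ss_total < 1e-300:
        warnings.warn("zero total variance: raters agree trivially, ICC = 1", stacklevel=2)
        return ICCResult(1.0, "two-way random, absolute agreement, single measure", 0.0, 0.0, 0.0)
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    icc = (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    )
    return ICCResult(
        icc=float(icc),
        model="two-way random, absolute agreement, single measure",
        ms_rows=float(ms_rows),
        ms_cols=float(ms_cols),
        ms_error=float(ms_err),
    )
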