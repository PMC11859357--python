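"""Per-case and cohort statistics for OGTT glucose-tracking experiments.

Each case is a time series of reference blood glucose Cg (mean of two
fingertip meter readings every 5 min) and the differential absorbance
A_D at 1550 nm.  The per-case analysis is an ordinary least-squares line
predicting Cg from A_D, its Pearson correlation R, and the RMSE of the
fitted line against the reference glucose (so RMSE is in mmol/L).  Cases
are aggregated into R bins at 0.85 / 0.7 / 0.5 with the cohort-average
RMSE — the summary used to compare the blood-flow pre-stimulated and
control conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "OGTTCase",
    "CaseFit",
    "CohortSummary",
    "R_BIN_LABELS",
    "fit_case",
    "summarize_cohort",
]

# Bin edges follow the strict-inequality labels of the cohort table:
# a case with R exactly at an edge falls into the lower bin.
R_BIN_EDGES = (0.85, 0.7, 0.5)
R_BIN_LABELS = ("R>0.85", "0.85>=R>0.7", "0.7>=R>0.5", "R<=0.5")

CONDITIONS = ("pre_stimulated", "control")


class DegenerateFitError(ValueError):
    """The A_D series has no variance; the calibration line is undefined."""


@dataclass(frozen=True)
class OGTTCase:
    """One subject's OGTT trace: reference glucose and A_D(1550 nm)."""

    time: np.ndarray  # minutes
    cg: np.ndarray  # mmol/L, mean of two meter readings
    ad_1550: np.ndarray  # a.u.
    condition: str
    subject_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        cg = np.asarray(self.cg, dtype=float)
        ad = np.asarray(self.ad_1550, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "cg", cg)
        object.__setattr__(self, "ad_1550", ad)
        if not (t.shape == cg.shape == ad.shape):
            raise ValueError("time, cg and ad_1550 must have equal length")
        if t.size < 3:
            raise ValueError("an OGTT case needs at least 3 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(cg <= 0):
            raise ValueError("reference glucose must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    @property
    def n(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class CaseFit:
    """OLS calibration Cg = slope·A_D + intercept with its R and RMSE."""

    slope: float  # mmol/L per a.u.
    intercept: float  # mmol/L
    r: float
    rmse: float  # mmol/L
    n: int

    def __post_init__(self) -> None:
        if not (abs(self.r) <= 1.0 + 1e-12):
            raise ValueError("|r| cannot exceed 1")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level R-bin counts and average RMSE for one condition."""

    counts: dict
    average_rmse: float
    n_cases: int
    condition: str

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_cases:
            raise ValueError("bin counts must sum to the number of cases")


def fit_case(case: OGTTCase) -> CaseFit:
    """Fit the per-case calibration line and its error statistics.

    Glucose is regressed on A_D so residuals — and hence the RMSE — are in
    mmol/L, matching how a linear prediction model would be scored.
    """
    ad = case.ad_1550
    cg = case.cg
    if np.std(ad) == 0:
        raise DegenerateFitError("A_D series is constant; cannot calibrate")
    res = stats.linregress(ad, cg)
    pred = res.slope * ad + res.intercept
    rmse = float(np.sqrt(np.mean((pred - cg) ** 2)))
    return CaseFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        rmse=rmse,
        n=case.n,
    )


def bin_r(r: float) -> str:
    """Assign a correlation coefficient to its cohort-table bin."""
    if r > R_BIN_EDGES[0]:
        return R_BIN_LABELS[0]
    if r > R_BIN_EDGES[1]:
        return R_BIN_LABELS[1]
    if r > R_BIN_EDGES[2]:
        return R_BIN_LABELS[2]
    return R_BIN_LABELS[3]


def summarize_cohort(fits: Sequence[CaseFit], condition: str) -> CohortSummary:
    """Bin case correlations and average the per-case RMSE."""
    if len(fits) == 0:
        raise ValueError("no fits to summarise")
    counts = {label: 0 for label in R_BIN_LABELS}
    for f in fits:
        counts[bin_r(f.r)] += 1
    return CohortSummary(
        counts=counts,
        average_rmse=float(np.mean([f.rmse for f in fits])),
        n_cases=len(fits),
        condition=condition,
    )
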