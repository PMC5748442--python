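"""Prediction-performance statistics for AUC estimators.

Relative prediction errors in percent,

    PE_i  = (AUC_pred_i - AUC_obs_i) / AUC_obs_i * 100
    MPE   = mean(PE)          (bias)
    MAPE  = mean(|PE|)        (precision)
    RMSE  = sqrt(mean(PE^2))

plus counts of predictions outside the +/-20 % clinical error boundary and
a symmetry check of the PE distribution (sample skewness, range, sign test
for median zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PerformanceReport", "ErrorDistributionSummary", "performance", "error_distribution_check"]


@dataclass(frozen=True)
class PerformanceReport:
    pe: np.ndarray  # per-subject relative prediction errors, %
    mpe: float
    mape: float
    rmse: float
    n_above_20: int  # PE > +20 %
    n_below_m20: int  # PE < -20 %
    n: int


@dataclass(frozen=True)
class ErrorDistributionSummary:
    skewness: float
    pe_min: float
    pe_max: float
    sign_test_p: float


def performance(pred, obs) -> PerformanceReport:
    """Bias/precision summary of predicted vs observed AUCs."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be equal-length and non-empty")
    if np.any(obs <= 0):
        raise ValueError("observed AUCs must be positive")
    pe = (pred - obs) / obs * 100.0
    return PerformanceReport(
        pe=pe,
        mpe=float(np.mean(pe)),
        mape=float(np.mean(np.abs(pe))),
        rmse=float(np.sqrt(np.mean(pe**2))),
        n_above_20=int(np.sum(pe > 20.0)),
        n_below_m20=int(np.sum(pe < -20.0)),
        n=pe.size,
    )


def error_distribution_check(pe) -> ErrorDistributionSummary:
    """Symmetry and range of a prediction-error vector.

    Sample skewness (g1 = m3 / m2**1.5), min/max, and a two-sided sign test
    for a zero median (exact zeros dropped).
    """
    pe = np.asarray(pe, dtype=float)
    if pe.size < 3:
        raise ValueError("need at least 3 errors")
    nonzero = pe[pe != 0]
    if nonzero.size == 0:
        p = 1.0
    else:
        p = stats.binomtest(int(np.sum(nonzero > 0)), nonzero.size, 0.5).pvalue
    return ErrorDistributionSummary(
        skewness=float(stats.skew(pe, bias=True)),
        pe_min=float(pe.min()),
        pe_max=float(pe.max()),
        sign_test_p=float(p),
    )
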