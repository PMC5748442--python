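"""Non-compartmental AUC(0-inf) estimation.

Partial areas use the linear-up/log-down rule (linear trapezoid on rising
or flat segments and whenever a concentration is zero, log-trapezoid on
falling segments).  The terminal slope lambda_z comes from a log-linear
regression over the tail window with the best adjusted R2 (>= 3 points,
peak excluded), and AUC(0-inf) = AUC(0-last) + C_last / lambda_z.

Dosing is an infusion starting at t = 0, so profiles whose first sample is
later than 0 are anchored at (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Subject
from .exceptions import EstimationError

__all__ = ["NcaResult", "LambdaZResult", "auc_segment", "lambda_z", "auc_inf", "auc_inf_subject"]


@dataclass(frozen=True)
class LambdaZResult:
    lambda_z: float  # 1/h
    n_points: int
    adj_r2: float
    intercept: float  # log-scale intercept of the terminal regression


@dataclass(frozen=True)
class NcaResult:
    auc_last: float
    auc_inf: float
    lambda_z: float
    extrapolated_fraction: float
    n_points_lambda_z: int

    def __post_init__(self) -> None:
        if not (self.auc_inf >= self.auc_last > 0):
            raise ValueError("requires auc_inf >= auc_last > 0")
        if self.lambda_z <= 0:
            raise ValueError("lambda_z must be positive")
        if not (0 <= self.extrapolated_fraction < 1):
            raise ValueError("extrapolated fraction must lie in [0, 1)")


def auc_segment(t1: float, c1: float, t2: float, c2: float) -> float:
    """Partial AUC of one segment, linear-up/log-down."""
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    if c1 < 0 or c2 < 0:
        raise ValueError("concentrations must be non-negative")
    dt = t2 - t1
    if c2 >= c1 or c1 == 0.0 or c2 == 0.0:
        return 0.5 * (c1 + c2) * dt
    return (c1 - c2) * dt / np.log(c1 / c2)


def lambda_z(times, concs) -> LambdaZResult:
    """Terminal elimination rate constant by best-adjusted-R2 tail regression.

    Candidate windows are the trailing ``m >= 3`` points strictly after the
    peak; the window with the highest adjusted R2 wins (ties within 1e-4 go
    to the window with more points).  A non-negative slope in every window
    is an estimation error.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    keep = c > 0
    t, c = t[keep], c[keep]
    if t.size < 3:
        raise EstimationError("lambda_z needs at least 3 positive-concentration points")
    order = np.argsort(t)
    t, c = t[order], c[order]
    peak = int(np.argmax(c))
    best: LambdaZResult | None = None
    n = t.size
    for start in range(peak + 1, n - 2):
        tt, lc = t[start:], np.log(c[start:])
        m = tt.size
        slope, intercept = np.polyfit(tt, lc, 1)
        if slope >= 0:
            continue
        resid = lc - (slope * tt + intercept)
        sst = np.sum((lc - lc.mean()) ** 2)
        r2 = 1.0 if sst == 0 else 1.0 - np.sum(resid**2) / sst
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
        if best is None or adj > best.adj_r2 + 1e-4 or (abs(adj - best.adj_r2) <= 1e-4 and m > best.n_points):
            best = LambdaZResult(-slope, m, adj, intercept)
    if best is None:
        raise EstimationError("no tail window with a negative terminal slope")
    return best


def auc_inf(times, concs) -> NcaResult:
    """AUC(0-inf) by linear-up/log-down with log-linear tail extrapolation.

    BLQ records must already be removed.  An anchor (0, 0) is inserted when
    the first sample is drawn after the infusion start.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size != c.size or t.size == 0:
        raise ValueError("times and concs must be equal-length, non-empty")
    order = np.argsort(t)
    t, c = t[order], c[order]
    if t[0] < 0:
        raise ValueError("times must be non-negative")
    lz = lambda_z(t, c)
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[0.0], c])
    auc_last = sum(auc_segment(t[i], c[i], t[i + 1], c[i + 1]) for i in range(t.size - 1))
    tail = c[-1] / lz.lambda_z
    total = auc_last + tail
    return NcaResult(
        auc_last=auc_last,
        auc_inf=total,
        lambda_z=lz.lambda_z,
        extrapolated_fraction=tail / total,
        n_points_lambda_z=lz.n_points,
    )


def auc_inf_subject(subject: Subject) -> NcaResult:
    """NCA AUC(0-inf) of one subject's non-BLQ records."""
    recs = subject.observed()
    return auc_inf([r.time for r in recs], [r.conc for r in recs])
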