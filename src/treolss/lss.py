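"""Regression-based limited sampling strategies (LSS).

A limited sampling strategy predicts the full exposure AUC(0-inf) from the
treosulfan concentrations at two or three post-infusion sampling times via
an ordinary-least-squares equation

    AUC_pred = b0 + sum_k b_k * C(t_k).

Candidate time sets are drawn from the 10-point design grid, excluding
samples during the infusion (the end-of-infusion time itself is allowed)
and the 12 h sample.  Strategies are ranked by adjusted R2 on a learning
half of the cohort and validated on the held-out half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import Dataset, Subject
from .exceptions import ConfigurationError, EstimationError
from .nca import auc_inf_subject

__all__ = [
    "LimitedSamplingRegressor",
    "LSSModel",
    "split_learning_validation",
    "candidate_subsets",
    "nca_reference_aucs",
    "fit_lss",
    "rank_strategies",
    "predict_auc",
]


class LimitedSamplingRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares of AUC on a few timed concentrations.

    A deliberately small sklearn-compatible estimator: ``fit(X, y)`` with
    ``X`` the (n_subjects, n_times) concentration matrix and ``y`` the
    reference AUCs.  Exposes ``coef_``, ``intercept_``, ``adj_r2_``.
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per y entry")
        n, p = X.shape
        design = np.column_stack([np.ones(n), X]) if self.fit_intercept else X
        if n <= design.shape[1]:
            raise EstimationError("need more observations than regression coefficients")
        coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            raise EstimationError("singular design matrix (duplicated sampling time?)")
        fitted = design @ coef
        sse = float(np.sum((y - fitted) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if sst == 0 else 1.0 - sse / sst
        dof = n - p - (1 if self.fit_intercept else 0)
        self.intercept_ = float(coef[0]) if self.fit_intercept else 0.0
        self.coef_ = coef[1:] if self.fit_intercept else coef
        self.r2_ = r2
        self.adj_r2_ = 1.0 - (1.0 - r2) * (n - 1) / dof
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


@dataclass(frozen=True)
class LSSModel:
    """A sampling-time set plus its AUC predictor.

    ``mode`` is ``"regression"`` (OLS equation) or ``"bayesian"`` (the time
    set is used for MAP estimation; coefficients are unused).  The study
    considers 2- and 3-point strategies; single-time models are permitted
    for degenerate/teaching cases.
    """

    times: tuple[float, ...]
    intercept: float = 0.0
    coefficients: tuple[float, ...] = ()
    adj_r2: float = float("nan")
    mode: str = "regression"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.times) < 1:
            raise ValueError("an LSS needs at least one sampling time")
        if tuple(sorted(self.times)) != tuple(self.times):
            raise ValueError("times must be sorted ascending")
        if self.mode == "regression" and len(self.coefficients) != len(self.times):
            raise ValueError("one coefficient per sampling time required")
        if self.mode not in ("regression", "bayesian"):
            raise ValueError("mode must be 'regression' or 'bayesian'")


def split_learning_validation(
    dataset: Dataset, fraction: float = 0.5, seed: int | None = None
) -> tuple[Dataset, Dataset]:
    """Random subject-level split into learning and validation subsets."""
    if not (0 < fraction < 1):
        raise ConfigurationError("fraction must lie in (0, 1)")
    if dataset.n_subjects < 4:
        raise ConfigurationError("need at least 4 subjects to split")
    rng = np.random.default_rng(seed)
    ids = [s.id for s in dataset.subjects]
    perm = rng.permutation(len(ids))
    n_learn = int(round(dataset.n_subjects * fraction))
    learn_ids = {ids[i] for i in perm[:n_learn]}
    learning = Dataset([s for s in dataset.subjects if s.id in learn_ids], dict(dataset.meta))
    validation = Dataset([s for s in dataset.subjects if s.id not in learn_ids], dict(dataset.meta))
    return learning, validation


def candidate_subsets(candidate_times, k: int, t_inf: float) -> list[tuple[float, ...]]:
    """All k-subsets of the grid usable as an LSS for a given infusion length.

    Times strictly before the end of infusion and the 12 h sample are
    excluded; the end-of-infusion time itself is allowed (the published 2 h
    equations for 2 h infusions sample exactly at end of infusion).
    """
    if k not in (2, 3):
        raise ConfigurationError("strategies use 2 or 3 samples")
    usable = [float(t) for t in candidate_times if t >= t_inf and t != 12.0]
    return [tuple(c) for c in combinations(sorted(usable), k)]


def nca_reference_aucs(dataset: Dataset) -> dict[str, float]:
    """Reference ('observed') AUC(0-inf) per subject from NCA on all samples."""
    return {s.id: auc_inf_subject(s).auc_inf for s in dataset.subjects}


def _design_rows(subjects: list[Subject], times, auc_ref: dict[str, float]):
    X, y = [], []
    for s in subjects:
        try:
            X.append(s.conc_at(times))
        except KeyError:
            continue  # subject lacks a usable (non-BLQ) sample at a needed time
        y.append(auc_ref[s.id])
    if not X:
        raise EstimationError("no subject has usable records at all requested times")
    return np.asarray(X), np.asarray(y)


def fit_lss(subjects: list[Subject], times, auc_ref: dict[str, float], **meta) -> LSSModel:
    """OLS fit of the reference AUC on concentrations at ``times``."""
    times = tuple(sorted(float(t) for t in times))
    X, y = _design_rows(subjects, times, auc_ref)
    reg = LimitedSamplingRegressor().fit(X, y)
    return LSSModel(
        times=times,
        intercept=reg.intercept_,
        coefficients=tuple(float(c) for c in reg.coef_),
        adj_r2=reg.adj_r2_,
        mode="regression",
        meta={"n_learning": len(y), **meta},
    )


def rank_strategies(
    subjects: list[Subject], subsets, auc_ref: dict[str, float]
) -> list[LSSModel]:
    """Exhaustive OLS fit over candidate subsets, best adjusted R2 first.

    Ties break deterministically toward the earliest, then fewest, sampling
    times; the result is invariant to subject ordering.
    """
    models = [fit_lss(subjects, ts, auc_ref) for ts in subsets]
    return sorted(models, key=lambda m: (-m.adj_r2, m.times, len(m.times)))


def predict_auc(lss: LSSModel, concentrations) -> float:
    """Predicted AUC from concentrations at exactly ``lss.times``.

    ``concentrations`` is a sequence ordered as ``lss.times`` or a mapping
    time -> concentration.
    """
    if lss.mode != "regression":
        raise ValueError("predict_auc applies to regression-mode strategies")
    if isinstance(concentrations, dict):
        try:
            conc = [concentrations[t] for t in lss.times]
        except KeyError as exc:
            raise KeyError(f"missing concentration at t={exc.args[0]} h") from exc
    else:
        conc = list(concentrations)
        if len(conc) != len(lss.times):
            raise ValueError("one concentration per sampling time required")
    return float(lss.intercept + np.dot(lss.coefficients, conc))
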