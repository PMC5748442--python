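"""Bayesian individual estimation from sparse samples.

With the population model fixed, the individual random effects eta are
estimated from the few concentrations of a limited sampling strategy by
maximising the posterior (MAP, default) or by Metropolis-within-Gibbs
sampling of the posterior mean.  The individual AUC(0-inf) then follows
from dose / Cl_i.

The objective minimised is -2 log posterior (up to a constant),

    sum_j [ (c_obs_j - f_j)^2 / (b f_j)^2 + 2 ln(b f_j) ] + eta' Omega^-1 eta,

with f_j the model prediction at the j-th sampling time and Omega the IIV
covariance restricted to the eta-carrying parameters (Cl, V1, Q).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import pkmodel
from .cohort import Subject
from .exceptions import EstimationError
from .pkmodel import PKParameters, PopulationModel, RandomEffects

__all__ = ["IndividualEstimate", "map_objective", "estimate_individual", "conditional_mean_estimate"]

_TINY = 1e-12


@dataclass(frozen=True)
class IndividualEstimate:
    eta_hat: RandomEffects
    params_hat: PKParameters
    auc_hat: float  # mg*h/L, = total_dose / cl_hat
    objective_value: float
    mode: str = "map"  # "map" or "conditional_mean"


def _subject_data(subject: Subject, times=None):
    recs = subject.observed()
    if times is not None:
        wanted = {round(float(t), 9) for t in times}
        recs = [r for r in recs if round(r.time, 9) in wanted]
    if not recs:
        raise ValueError("subject has no usable (non-BLQ) records at the requested times")
    t = np.array([r.time for r in recs])
    y = np.array([r.conc for r in recs])
    return t, y


def _active_dims(pop: PopulationModel):
    omega = pop.omega_matrix()
    active = np.where(np.diag(omega) > _TINY**2)[0]
    if active.size == 0:
        return active, None
    sub = omega[np.ix_(active, active)]
    return active, np.linalg.inv(sub)


def _neg2_obj(pop, subject, t, y, eta_vec, omega_inv, active, clip=False):
    params = pkmodel.individual_parameters(pop, subject.bodyweight, RandomEffects(*eta_vec))
    f = pkmodel.concentration(params, subject.regimen.total_dose, subject.regimen.t_inf, t)
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        if not clip:
            raise EstimationError("zero predicted concentration at an observation time")
        f = np.maximum(f, _TINY)
    b = pop.prop_error_b
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        f = np.minimum(f, 1e150)
        sd = np.sqrt((b * f) ** 2 + pop.add_error**2)
        data = np.sum(((y - f) / sd) ** 2 + 2.0 * np.log(sd))
    prior = 0.0
    if omega_inv is not None:
        e = eta_vec[active]
        prior = float(e @ omega_inv @ e)
    out = float(data + prior)
    return out if np.isfinite(out) else np.inf


def map_objective(pop: PopulationModel, subject: Subject, eta: RandomEffects, times=None) -> float:
    """-2 log posterior (up to a constant) of eta given the subject's records."""
    t, y = _subject_data(subject, times)
    active, omega_inv = _active_dims(pop)
    return _neg2_obj(pop, subject, t, y, eta.as_array(), omega_inv, active)


def _minimize(pop, subject, t, y, n_starts, seed):
    active, omega_inv = _active_dims(pop)
    if active.size == 0:
        return np.zeros(3), _neg2_obj(pop, subject, t, y, np.zeros(3), omega_inv, active)

    def fun(x):
        eta = np.zeros(3)
        eta[active] = x
        return _neg2_obj(pop, subject, t, y, eta, omega_inv, active, clip=True)

    rng = np.random.default_rng(seed)
    omega = pop.omega_matrix()[np.ix_(active, active)]
    chol = np.linalg.cholesky(omega + 1e-14 * np.eye(active.size))
    starts = [np.zeros(active.size)]
    starts += [chol @ rng.standard_normal(active.size) for _ in range(max(n_starts - 1, 0))]
    bounds = [(-8.0, 8.0)] * active.size
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = optimize.minimize(fun, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500})
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    if best_x is None:
        raise EstimationError("MAP optimisation failed from every start")
    # polish the winning start with a short simplex run (gradient-free)
    res = optimize.minimize(fun, best_x, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 500})
    if res.fun < best_f:
        best_x, best_f = res.x, float(res.fun)
    eta = np.zeros(3)
    eta[active] = best_x
    return eta, best_f


def _finish(pop, subject, eta_vec, obj, mode) -> IndividualEstimate:
    eta = RandomEffects(*eta_vec)
    params = pkmodel.individual_parameters(pop, subject.bodyweight, eta)
    return IndividualEstimate(
        eta_hat=eta,
        params_hat=params,
        auc_hat=subject.regimen.total_dose / params.cl,
        objective_value=obj,
        mode=mode,
    )


def estimate_individual(
    pop: PopulationModel,
    subject: Subject,
    times=None,
    n_starts: int = 5,
    seed: int = 0,
) -> IndividualEstimate:
    """MAP estimate of eta (and hence AUC) from the samples at ``times``.

    Multi-start Nelder-Mead: one start at the prior mode plus ``n_starts-1``
    draws from the prior.
    """
    t, y = _subject_data(subject, times)
    eta_vec, obj = _minimize(pop, subject, t, y, n_starts, seed)
    return _finish(pop, subject, eta_vec, obj, "map")


def conditional_mean_estimate(
    pop: PopulationModel,
    subject: Subject,
    times=None,
    n_mcmc: int = 4000,
    seed: int = 0,
) -> IndividualEstimate:
    """Posterior-mean eta by Metropolis-within-Gibbs sampling.

    The first half of the chain is burn-in with Robbins-Monro adaptation of
    the per-component proposal scales toward ~40 % acceptance.
    """
    t, y = _subject_data(subject, times)
    active, omega_inv = _active_dims(pop)
    if active.size == 0:
        return _finish(pop, subject, np.zeros(3), _neg2_obj(pop, subject, t, y, np.zeros(3), omega_inv, active), "conditional_mean")
    rng = np.random.default_rng(seed)
    eta_map, _ = _minimize(pop, subject, t, y, 3, seed)
    x = eta_map[active].copy()

    def logpost(xv):
        eta = np.zeros(3)
        eta[active] = xv
        try:
            return -0.5 * _neg2_obj(pop, subject, t, y, eta, omega_inv, active)
        except EstimationError:
            return -np.inf

    lp = logpost(x)
    scales = np.full(active.size, 0.3)
    burn = n_mcmc // 2
    draws = np.empty((n_mcmc - burn, active.size))
    for it in range(n_mcmc):
        for d in range(active.size):
            prop = x.copy()
            prop[d] += scales[d] * rng.standard_normal()
            lp_prop = logpost(prop)
            accept = np.log(rng.uniform()) < lp_prop - lp
            if accept:
                x, lp = prop, lp_prop
            if it < burn:  # stochastic approximation toward 40 % acceptance
                scales[d] *= np.exp((1.0 if accept else 0.0) - 0.4) ** (5.0 / (it + 10))
        if it >= burn:
            draws[it - burn] = x
    eta = np.zeros(3)
    eta[active] = draws.mean(axis=0)
    obj = _neg2_obj(pop, subject, t, y, eta, omega_inv, active)
    return _finish(pop, subject, eta, obj, "conditional_mean")
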