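"""Nonlinear mixed-effects estimation of the population PK model.

Estimation is by stochastic-approximation EM (SAEM): the E-step runs >= 4
parallel Metropolis-Hastings chains per subject on the log-scale individual
parameters (one independent prior-proposal sweep plus adaptive
random-walk sweeps), and the M-step updates the log-normal typical values,
the IIV covariance and the residual-error parameters from stochastically
approximated sufficient statistics.  Structural parameters that carry no
random effect (e.g. V2 in the final model) and non-closed-form error
models are updated by a Robbins-Monro damped numerical minimisation of the
complete-data objective.

The marginal -2 log-likelihood (MOFV) is computed by importance sampling
around each subject's MAP random effect with a Laplace (Gaussian)
proposal; standard errors come from a numerically differentiated Hessian
of the fixed-draw importance-sampled -2LL.

One-, two- and three-compartment structures are supported (the three-
compartment solution via eigendecomposition of the rate matrix) for the
structural-selection harness; the two-compartment allometric model is the
primary object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, special

from . import pkmodel
from .cohort import Dataset
from .exceptions import ConfigurationError, EstimationError
from .pkmodel import PKParameters, PopulationModel

__all__ = [
    "FitStructure",
    "FitResult",
    "Minus2LL",
    "ModelComparison",
    "VpcSummary",
    "BootstrapResult",
    "marginal_minus2ll",
    "fit_population",
    "compare_models",
    "eta_shrinkage",
    "bootstrap",
    "pcvpc",
    "wald_covariate_test",
]

_PARAMS_BY_NCMT = {
    1: ("cl", "v1"),
    2: ("cl", "v1", "q", "v2"),
    3: ("cl", "v1", "q", "v2", "q3", "v3"),
}
_DEFAULT_IIV = {1: ("cl", "v1"), 2: ("cl", "v1", "q"), 3: ("cl", "v1", "q")}
#: allometric exponents of the final model: 0.75 for elimination clearance,
#: 1 for volumes, 0 for intercompartmental clearances (no weight effect).
_DEFAULT_EXPO = {"cl": 0.75, "v1": 1.0, "q": 0.0, "v2": 1.0, "q3": 0.0, "v3": 1.0}
_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class FitStructure:
    """Structural choices examined during model building."""

    n_compartments: int = 2
    error_model: str = "proportional"  # proportional | additive | combined
    allometric: bool = True
    estimate_exponents: bool = False
    covariance: str = "block"  # diagonal | block (Cl-V1 corr) | full
    iiv_params: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2, 3):
            raise ConfigurationError("n_compartments must be 1, 2 or 3")
        if self.error_model not in ("proportional", "additive", "combined"):
            raise ConfigurationError("unknown error model")
        if self.covariance not in ("diagonal", "block", "full"):
            raise ConfigurationError("unknown covariance structure")

    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAMS_BY_NCMT[self.n_compartments]

    @property
    def random_names(self) -> tuple[str, ...]:
        iiv = self.iiv_params if self.iiv_params is not None else _DEFAULT_IIV[self.n_compartments]
        return tuple(p for p in self.param_names if p in iiv)

    def default_exponents(self) -> np.ndarray:
        if not self.allometric:
            return np.zeros(len(self.param_names))
        return np.array([_DEFAULT_EXPO[p] for p in self.param_names])

    def corr_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (within random_names) of estimated correlations."""
        rn = self.random_names
        if self.covariance == "diagonal":
            return []
        if self.covariance == "block":
            if "cl" in rn and "v1" in rn:
                return [(rn.index("cl"), rn.index("v1"))]
            return []
        return [(i, j) for i in range(len(rn)) for j in range(i + 1, len(rn))]

    def n_parameters(self) -> int:
        p = len(self.param_names) + len(self.random_names) + len(self.corr_pairs())
        if self.estimate_exponents:
            p += len(self.random_names)
        p += 2 if self.error_model == "combined" else 1
        return p


@dataclass
class _State:
    mu: np.ndarray  # (P,) log typical values
    expo: np.ndarray  # (P,) allometric exponents
    omega: np.ndarray  # (R, R) IIV covariance (log scale)
    err_b: float  # proportional SD
    err_a: float  # additive SD, mg/L

    def copy(self) -> "_State":
        return _State(self.mu.copy(), self.expo.copy(), self.omega.copy(), self.err_b, self.err_a)


@dataclass
class _FitData:
    t: np.ndarray  # (S, M) padded times
    y: np.ndarray  # (S, M) padded concentrations
    mask: np.ndarray  # (S, M) 1 where a real observation sits
    bw: np.ndarray  # (S,)
    dose: np.ndarray  # (S,)
    tinf: np.ndarray  # (S,)
    x: np.ndarray  # (S,) log(bw / ref_weight)
    ids: list

    @property
    def n_subjects(self) -> int:
        return self.t.shape[0]

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())


def _prepare(dataset: Dataset, ref_weight: float = 70.0) -> _FitData:
    subs = dataset.subjects
    if not subs:
        raise ConfigurationError("dataset is empty")
    recs = [s.observed() for s in subs]
    if any(len(r) == 0 for r in recs):
        raise ConfigurationError("every subject needs at least one non-BLQ record")
    m = max(len(r) for r in recs)
    S = len(subs)
    t = np.zeros((S, m))
    y = np.zeros((S, m))
    mask = np.zeros((S, m))
    for i, rr in enumerate(recs):
        t[i, : len(rr)] = [r.time for r in rr]
        y[i, : len(rr)] = [r.conc for r in rr]
        mask[i, : len(rr)] = 1.0
    bw = np.array([s.bodyweight for s in subs])
    return _FitData(
        t=t,
        y=y,
        mask=mask,
        bw=bw,
        dose=np.array([s.regimen.total_dose for s in subs]),
        tinf=np.array([s.regimen.t_inf for s in subs]),
        x=np.log(bw / ref_weight),
        ids=[s.id for s in subs],
    )


# ---------------------------------------------------------------------------
# concentration for generic structures

def _conc_3cmt_scalar(cl, v1, q2, v2, q3, v3, dose, t_inf, t):
    k10, k12, k21 = cl / v1, q2 / v1, q2 / v2
    k13, k31 = q3 / v1, q3 / v3
    K = np.array([[-(k10 + k12 + k13), k21, k31], [k12, -k21, 0.0], [k13, 0.0, -k31]])
    lam, V = np.linalg.eig(K)
    Vin = np.linalg.inv(V)
    rate = dose / t_inf
    t = np.asarray(t, dtype=float)
    tau = np.minimum(t, t_inf)[..., None]
    te = np.maximum(t - t_inf, 0.0)[..., None]
    lam_ = lam[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(
            np.abs(lam_) < 1e-12, tau, (np.exp(lam_ * tau) - 1.0) / lam_
        ) * np.exp(lam_ * te)
    amt1 = (V[0, :][None, :] * Vin[:, 0][None, :] * g).sum(axis=-1) * rate
    return np.maximum(np.real(amt1), 0.0) / v1


def _conc_generic(structure: FitStructure, vals: dict, dose, t_inf, t):
    """Concentration for broadcast parameter arrays ``vals`` and times ``t``.

    ``vals[name]`` must broadcast against ``dose``/``t_inf``; ``t`` adds a
    trailing time axis.
    """
    if structure.n_compartments == 1:
        return pkmodel._profile(vals["cl"], vals["v1"], 0.0, 1.0, dose, t_inf, t)
    if structure.n_compartments == 2:
        return pkmodel._profile(vals["cl"], vals["v1"], vals["q"], vals["v2"], dose, t_inf, t)
    # 3-compartment: loop over the leading (subject/chain) axes
    b = np.broadcast(vals["cl"], np.asarray(dose))
    out = np.empty(b.shape + np.asarray(t).shape[-1:])
    arrs = {k: np.broadcast_to(v, b.shape) for k, v in vals.items()}
    dose_b = np.broadcast_to(dose, b.shape)
    tinf_b = np.broadcast_to(t_inf, b.shape)
    t_b = np.broadcast_to(t, b.shape + np.asarray(t).shape[-1:])
    for idx in np.ndindex(b.shape):
        out[idx] = _conc_3cmt_scalar(
            arrs["cl"][idx], arrs["v1"][idx], arrs["q"][idx], arrs["v2"][idx],
            arrs["q3"][idx], arrs["v3"][idx], dose_b[idx], tinf_b[idx], t_b[idx],
        )
    return out


def _error_sd2(state: _State, f):
    return state.err_a**2 + (state.err_b * f) ** 2


def _predict_f(data: _FitData, structure: FitStructure, state: _State, phi):
    """Model predictions (S, C, M) given log individual params phi (S, C, R)."""
    names = structure.param_names
    rnames = structure.random_names
    C = phi.shape[1] if phi is not None else 1
    vals = {}
    for j, name in enumerate(names):
        if name in rnames and phi is not None:
            vals[name] = np.exp(phi[:, :, rnames.index(name), None])
        else:
            v = np.exp(state.mu[j] + state.expo[j] * data.x)
            vals[name] = v[:, None, None]
    return _conc_generic(
        structure,
        vals,
        data.dose[:, None, None],
        data.tinf[:, None, None],
        data.t[:, None, :],
    )


def _loglik_obs(data: _FitData, state: _State, f):
    """Observation log-likelihood per (subject, chain) for predictions f."""
    sd2 = np.maximum(_error_sd2(state, f), 1e-280)
    r = data.y[:, None, :] - f
    terms = (r * r / sd2 + np.log(sd2) + _LOG2PI) * data.mask[:, None, :]
    return -0.5 * terms.sum(axis=2)


# ---------------------------------------------------------------------------
# SAEM

def _init_state(data: _FitData, structure: FitStructure, init: PopulationModel | None) -> _State:
    names = structure.param_names
    R = len(structure.random_names)
    expo = structure.default_exponents()
    if init is not None:
        lut = init.to_dict()
        mu = np.array([np.log(lut["theta"].get(p, 1.0)) for p in names])
        for j, p in enumerate(names):
            if p in lut["beta"]:
                expo[j] = lut["beta"][p]
        omega = np.eye(R) * 0.09
        rn = structure.random_names
        for i, p in enumerate(rn):
            omega[i, i] = max(lut["omega"].get(p, 0.3), 1e-3) ** 2
        if "cl" in rn and "v1" in rn:
            i, j = rn.index("cl"), rn.index("v1")
            omega[i, j] = omega[j, i] = init.corr_cl_v1 * np.sqrt(omega[i, i] * omega[j, j])
        return _State(mu, expo, omega, max(init.prop_error_b, 1e-3), max(init.add_error, 0.0))

    # data-driven heuristics: NCA clearance, Cmax-based central volume
    from . import nca as _nca

    cl_i, vz_i, v1_i = [], [], []
    for i in range(data.n_subjects):
        m = data.mask[i] > 0
        tt, yy = data.t[i, m], data.y[i, m]
        cmax = yy.max()
        try:
            res = _nca.auc_inf(tt, yy)
            cl = data.dose[i] / res.auc_inf
            vz_i.append(cl / res.lambda_z)
        except (EstimationError, ValueError):
            cl = data.dose[i] / max(np.trapezoid(yy, tt) * 1.5, 1e-9)
            vz_i.append(cl * 4.0)
        cl_i.append(cl)
        v1_i.append(0.5 * data.dose[i] / cmax)
    cl_i, vz_i, v1_i = map(np.asarray, (cl_i, vz_i, v1_i))
    guess = {
        "cl": np.median(np.log(cl_i) - expo[names.index("cl")] * data.x),
        "v1": np.median(np.log(v1_i) - expo[names.index("v1")] * data.x),
    }
    if "q" in names:
        guess["q"] = guess["cl"] + np.log(0.15)
        guess["v2"] = np.median(np.log(0.4 * vz_i) - expo[names.index("v2")] * data.x)
    if "q3" in names:
        guess["q3"] = guess["cl"] + np.log(0.05)
        guess["v3"] = guess["v2"]
    mu = np.array([guess[p] for p in names])
    return _State(mu, expo, np.eye(R) * 0.09, 0.2, 0.0)


def _project_omega(omega: np.ndarray, structure: FitStructure) -> np.ndarray:
    R = omega.shape[0]
    out = np.diag(np.maximum(np.diag(omega), 1e-6))
    for i, j in structure.corr_pairs():
        corr = omega[i, j] / np.sqrt(out[i, i] * out[j, j])
        corr = np.clip(corr, -0.98, 0.98)
        out[i, j] = out[j, i] = corr * np.sqrt(out[i, i] * out[j, j])
    return out


def _mstep_numeric(data, structure, state, phi, f, what):
    """Damped numerical M-step for non-random typicals and combined error."""
    names = structure.param_names
    fixed_idx = [j for j, p in enumerate(names) if p not in structure.random_names]

    def resid_obj(mu_fixed, log_err=None):
        st = state.copy()
        for pos, j in enumerate(fixed_idx):
            st.mu[j] = mu_fixed[pos]
        if log_err is not None:
            st.err_a, st.err_b = np.exp(log_err)
        ff = _predict_f(data, structure, st, phi)
        return float(-2.0 * _loglik_obs(data, st, ff).mean(axis=1).sum())

    if what == "structural" and fixed_idx:
        x0 = state.mu[fixed_idx]
        res = optimize.minimize(resid_obj, x0, method="Nelder-Mead",
                                options={"maxiter": 30, "xatol": 1e-4, "fatol": 1e-4})
        return res.x
    if what == "combined":
        x0 = np.log([max(state.err_a, 1e-3), max(state.err_b, 1e-3)])
        res = optimize.minimize(lambda le: resid_obj(state.mu[fixed_idx], le), x0,
                                method="Nelder-Mead",
                                options={"maxiter": 30, "xatol": 1e-4, "fatol": 1e-4})
        return np.exp(res.x)
    return None


def _run_saem(data, structure, state, k1, k2, n_chains, rng, store_trace):
    S = data.n_subjects
    R = len(structure.random_names)
    rnames = structure.random_names
    names = structure.param_names
    rand_j = [names.index(p) for p in rnames]
    mx, mx2 = data.x.mean(), (data.x**2).mean()

    # initial phi at the prior mean
    c = state.mu[rand_j][None, :] + state.expo[rand_j][None, :] * data.x[:, None]  # (S,R)
    phi = np.repeat(c[:, None, :], n_chains, axis=1).astype(float)
    steps = np.full(R, 0.4)

    stat1 = np.zeros(R)
    statx = np.zeros(R)
    stat2 = np.zeros((R, R))
    stat_res = 0.1  # SA stat for the residual-error sufficient statistic
    trace = {"mu": [], "omega": [], "err": []} if store_trace else None
    mu_hist = []

    n_iter = k1 + k2
    for k in range(1, n_iter + 1):
        gamma = 1.0 if k <= k1 else 1.0 / (k - k1)
        om = _project_omega(state.omega, structure)
        om_chol = np.linalg.cholesky(om + 1e-12 * np.eye(R))
        om_inv = np.linalg.inv(om + 1e-12 * np.eye(R))
        c = state.mu[rand_j][None, :] + state.expo[rand_j][None, :] * data.x[:, None]
        # current-state likelihood of the carried-over chains (the M-step
        # moved the state, so cached values would be stale)
        ll = _loglik_obs(data, state, _predict_f(data, structure, state, phi))

        def lprior(p):
            d = p - c[:, None, :]
            return -0.5 * np.einsum("scr,rq,scq->sc", d, om_inv, d)

        # --- E-step: one independent-prior sweep
        z = rng.standard_normal((S, n_chains, R))
        prop = c[:, None, :] + z @ om_chol.T
        f_prop = _predict_f(data, structure, state, prop)
        ll_prop = _loglik_obs(data, state, f_prop)
        acc = np.log(rng.uniform(size=(S, n_chains))) < (ll_prop - ll)
        phi = np.where(acc[:, :, None], prop, phi)
        ll = np.where(acc, ll_prop, ll)

        # --- two adaptive random-walk (Metropolis-within-Gibbs) sweeps
        lpr = lprior(phi)
        for _sweep in range(2):
            for d in range(R):
                prop = phi.copy()
                prop[:, :, d] += steps[d] * rng.standard_normal((S, n_chains))
                f_prop = _predict_f(data, structure, state, prop)
                ll_prop = _loglik_obs(data, state, f_prop)
                lpr_prop = lprior(prop)
                acc = np.log(rng.uniform(size=(S, n_chains))) < (
                    ll_prop + lpr_prop - ll - lpr
                )
                phi = np.where(acc[:, :, None], prop, phi)
                ll = np.where(acc, ll_prop, ll)
                lpr = np.where(acc, lpr_prop, lpr)
                if k <= k1:  # constant-gain adaptation toward ~35 % acceptance
                    rate = acc.mean()
                    steps[d] = float(np.clip(steps[d] * np.exp(0.4 * (rate - 0.35)),
                                             1e-6, 5.0))

        # --- sufficient statistics (averaged over chains)
        f = _predict_f(data, structure, state, phi)
        s1 = phi.mean(axis=(0, 1))
        sx = (phi * data.x[:, None, None]).mean(axis=(0, 1))
        s2 = np.einsum("scr,scq->rq", phi, phi) / (S * n_chains)
        with np.errstate(divide="ignore", invalid="ignore"):
            if structure.error_model == "additive":
                res = ((data.y[:, None, :] - f) ** 2 * data.mask[:, None, :]).sum() / (
                    data.mask.sum() * n_chains
                )
            else:
                fr = np.maximum(f, 1e-12)
                res = (
                    ((data.y[:, None, :] - f) / fr) ** 2 * data.mask[:, None, :]
                ).sum() / (data.mask.sum() * n_chains)
        stat1 += gamma * (s1 - stat1)
        statx += gamma * (sx - statx)
        stat2 += gamma * (s2 - stat2)
        stat_res += gamma * (res - stat_res)

        # --- M-step: typicals / exponents / Omega in closed form
        if structure.estimate_exponents:
            A = np.array([[1.0, mx], [mx, mx2]])
            for r, j in enumerate(rand_j):
                a, b = np.linalg.solve(A, np.array([stat1[r], statx[r]]))
                state.mu[j], state.expo[j] = a, b
        else:
            for r, j in enumerate(rand_j):
                state.mu[j] = stat1[r] - state.expo[j] * mx
        a_vec = state.mu[rand_j]
        b_vec = state.expo[rand_j]
        omega = (
            stat2
            - np.outer(a_vec, stat1) - np.outer(stat1, a_vec)
            - np.outer(b_vec, statx) - np.outer(statx, b_vec)
            + np.outer(a_vec, a_vec)
            + mx * (np.outer(a_vec, b_vec) + np.outer(b_vec, a_vec))
            + mx2 * np.outer(b_vec, b_vec)
        )
        omega = _project_omega(omega, structure)
        if k <= k1:
            # simulated annealing: variances shrink at most 5 % per burn-in
            # iteration so the chains keep mixing while the typicals converge
            prev = np.diag(state.omega)
            floor = 0.95 * prev
            scale = np.sqrt(np.maximum(np.diag(omega), floor) / np.maximum(np.diag(omega), 1e-300))
            omega = omega * np.outer(scale, scale)
        state.omega = omega

        if structure.error_model == "proportional":
            b_new = float(np.sqrt(max(stat_res, 1e-8)))
            state.err_b = max(b_new, np.sqrt(0.95) * state.err_b) if k <= k1 else b_new
        elif structure.error_model == "additive":
            a_new = float(np.sqrt(max(stat_res, 1e-8)))
            state.err_a = max(a_new, np.sqrt(0.95) * state.err_a) if k <= k1 else a_new
        else:
            a_new, b_new = _mstep_numeric(data, structure, state, phi, f, "combined")
            state.err_a += gamma * (a_new - state.err_a)
            state.err_b += gamma * (b_new - state.err_b)

        fixed_idx = [j for j, p in enumerate(names) if p not in rnames]
        if fixed_idx:
            mu_new = _mstep_numeric(data, structure, state, phi, f, "structural")
            state.mu[fixed_idx] += gamma * (mu_new - state.mu[fixed_idx])

        mu_hist.append(state.mu.copy())
        if store_trace:
            trace["mu"].append(state.mu.copy())
            trace["omega"].append(np.sqrt(np.diag(state.omega)))
            trace["err"].append([state.err_a, state.err_b])

    # convergence: drift of typicals over the smoothing phase
    hist = np.array(mu_hist[k1:]) if k2 > 1 else np.array(mu_hist[-2:])
    if len(hist) >= 4:
        half = len(hist) // 2
        drift = np.abs(hist[half:].mean(axis=0) - hist[:half].mean(axis=0))
        converged = bool(np.all(drift < 0.05))
    else:
        converged = True
    if store_trace:
        trace = {k_: np.asarray(v) for k_, v in trace.items()}
    return state, converged, trace


# ---------------------------------------------------------------------------
# marginal likelihood by importance sampling

@dataclass(frozen=True)
class Minus2LL:
    value: float
    mc_se: float
    n_samples: int

    def __float__(self) -> float:
        return self.value


def _subject_neg2post(data, structure, state, i, om_inv, om_logdet):
    rnames = structure.random_names
    names = structure.param_names
    rand_j = [names.index(p) for p in rnames]
    m = data.mask[i] > 0
    tt, yy = data.t[i, m], data.y[i, m]
    c_i = state.mu[rand_j] + state.expo[rand_j] * data.x[i]
    R = len(rnames)

    def fun(eta):
        vals = {}
        for j, name in enumerate(names):
            if name in rnames:
                vals[name] = np.exp(c_i[rnames.index(name)] + eta[rnames.index(name)])
            else:
                vals[name] = np.exp(state.mu[j] + state.expo[j] * data.x[i])
        f = _conc_generic(structure, vals, data.dose[i], data.tinf[i], tt)
        sd2 = np.maximum(_error_sd2(state, f), 1e-280)
        dat = np.sum((yy - f) ** 2 / sd2 + np.log(sd2) + _LOG2PI)
        pri = float(eta @ om_inv @ eta) + om_logdet + R * _LOG2PI
        return float(dat + pri)

    return fun


def _map_etas(data, structure, state):
    """Per-subject MAP eta and Laplace proposal covariance."""
    R = len(structure.random_names)
    om = _project_omega(state.omega, structure)
    om_inv = np.linalg.inv(om + 1e-12 * np.eye(R))
    om_logdet = float(np.linalg.slogdet(om + 1e-12 * np.eye(R))[1])
    etas = np.zeros((data.n_subjects, R))
    covs = np.zeros((data.n_subjects, R, R))
    for i in range(data.n_subjects):
        fun = _subject_neg2post(data, structure, state, i, om_inv, om_logdet)
        res = optimize.minimize(fun, np.zeros(R), method="L-BFGS-B",
                                bounds=[(-8, 8)] * R, options={"maxiter": 300})
        etas[i] = res.x
        h = np.zeros((R, R))
        step = 1e-4
        f0 = fun(res.x)
        for a in range(R):
            ea = np.zeros(R); ea[a] = step
            f_p, f_m = fun(res.x + ea), fun(res.x - ea)
            h[a, a] = (f_p - 2 * f0 + f_m) / step**2
            for b in range(a + 1, R):
                eb = np.zeros(R); eb[b] = step
                h[a, b] = h[b, a] = (
                    fun(res.x + ea + eb) - fun(res.x + ea - eb)
                    - fun(res.x - ea + eb) + fun(res.x - ea - eb)
                ) / (4 * step**2)
        try:
            cov = 2.0 * np.linalg.inv(h)
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            cov = om.copy()
        covs[i] = cov
    return etas, covs


def _is_logweights(data, structure, state, etas, covs, z):
    """Vectorised IS log-weights (S, N) for fixed standard-normal draws z."""
    S, N, R = z.shape
    rnames = structure.random_names
    names = structure.param_names
    rand_j = [names.index(p) for p in rnames]
    om = _project_omega(state.omega, structure)
    om_inv = np.linalg.inv(om + 1e-12 * np.eye(R))
    om_logdet = float(np.linalg.slogdet(om + 1e-12 * np.eye(R))[1])
    chols = np.linalg.cholesky(covs + 1e-12 * np.eye(R))
    eta = etas[:, None, :] + np.einsum("srq,snq->snr", chols, z)  # (S,N,R)
    logq = (
        -0.5 * (z**2).sum(axis=2)
        - np.log(np.abs(np.diagonal(chols, axis1=1, axis2=2))).sum(axis=1)[:, None]
        - 0.5 * R * _LOG2PI
    )
    c = state.mu[rand_j][None, None, :] + state.expo[rand_j][None, None, :] * data.x[:, None, None]
    vals = {}
    for j, name in enumerate(names):
        if name in rnames:
            vals[name] = np.exp(c[:, :, rnames.index(name), None] + eta[:, :, rnames.index(name), None])
        else:
            vals[name] = np.exp(state.mu[j] + state.expo[j] * data.x)[:, None, None]
    f = _conc_generic(
        structure, vals, data.dose[:, None, None], data.tinf[:, None, None], data.t[:, None, :]
    )
    sd2 = np.maximum(_error_sd2(state, f), 1e-280)
    r = data.y[:, None, :] - f
    ll = -0.5 * ((r * r / sd2 + np.log(sd2) + _LOG2PI) * data.mask[:, None, :]).sum(axis=2)
    lp = -0.5 * (np.einsum("snr,rq,snq->sn", eta, om_inv, eta) + om_logdet + R * _LOG2PI)
    return ll + lp - logq


def _is_minus2ll(data, structure, state, etas, covs, z):
    logw = _is_logweights(data, structure, state, etas, covs, z)
    N = z.shape[1]
    logm = special.logsumexp(logw, axis=1) - np.log(N)
    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    mhat = w.mean(axis=1)
    se_log = w.std(axis=1) / (np.sqrt(N) * np.maximum(mhat, 1e-300))
    value = float(-2.0 * logm.sum())
    mc_se = float(2.0 * np.sqrt((se_log**2).sum()))
    return value, mc_se


def _state_from_pop(pop: PopulationModel):
    omegas = {"cl": pop.omega_cl, "v1": pop.omega_v1, "q": pop.omega_q}
    iiv = tuple(p for p in ("cl", "v1", "q") if omegas[p] > 0)
    cov = "block" if ("cl" in iiv and "v1" in iiv and pop.corr_cl_v1 != 0) else "diagonal"
    err = "proportional" if pop.add_error == 0 else ("combined" if pop.prop_error_b > 0 else "additive")
    structure = FitStructure(n_compartments=2, error_model=err, covariance=cov, iiv_params=iiv)
    t = pop.theta
    mu = np.log([t.cl, t.v1, t.q, t.v2]) if t.q > 0 else np.log([t.cl, t.v1, 1e-10, t.v2])
    R = len(structure.random_names)
    omega = np.zeros((R, R))
    for i, p in enumerate(structure.random_names):
        omega[i, i] = omegas[p] ** 2
    for i, j in structure.corr_pairs():
        omega[i, j] = omega[j, i] = pop.corr_cl_v1 * np.sqrt(omega[i, i] * omega[j, j])
    state = _State(mu, pop.betas(), omega, pop.prop_error_b, pop.add_error)
    return structure, state


def marginal_minus2ll(
    pop: PopulationModel, dataset: Dataset, n_samples: int = 500, seed: int = 0
) -> Minus2LL:
    """-2 log marginal likelihood of a dataset under a fixed population model.

    Subject random effects are integrated out by importance sampling with a
    Laplace proposal centred at each subject's MAP eta.  Deterministic for
    a fixed seed; the Monte-Carlo SE is reported alongside the value.
    """
    structure, state = _state_from_pop(pop)
    data = _prepare(dataset, pop.ref_weight)
    if len(structure.random_names) == 0 or np.all(np.diag(state.omega) < 1e-12):
        f = _predict_f(data, structure, state, None)[:, 0, :]
        sd2 = np.maximum(_error_sd2(state, f), 1e-280)
        r = (data.y - f) ** 2 / sd2 + np.log(sd2) + _LOG2PI
        return Minus2LL(float((r * data.mask).sum()), 0.0, 0)
    etas, covs = _map_etas(data, structure, state)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((data.n_subjects, n_samples, len(structure.random_names)))
    value, mc_se = _is_minus2ll(data, structure, state, etas, covs, z)
    return Minus2LL(value, mc_se, n_samples)


# ---------------------------------------------------------------------------
# packing for standard errors

def _pack_names(structure: FitStructure):
    names = [f"theta_{p}" for p in structure.param_names]
    if structure.estimate_exponents:
        names += [f"beta_{p}" for p in structure.random_names]
    names += [f"omega_{p}" for p in structure.random_names]
    rn = structure.random_names
    names += [f"corr_{rn[i]}_{rn[j]}" for i, j in structure.corr_pairs()]
    if structure.error_model in ("proportional", "combined"):
        names.append("b")
    if structure.error_model in ("additive", "combined"):
        names.append("a")
    return names


def _pack(state: _State, structure: FitStructure) -> np.ndarray:
    sd = np.sqrt(np.diag(state.omega))
    out = list(np.exp(state.mu))
    if structure.estimate_exponents:
        rand_j = [structure.param_names.index(p) for p in structure.random_names]
        out += list(state.expo[rand_j])
    out += list(sd)
    for i, j in structure.corr_pairs():
        out.append(state.omega[i, j] / max(sd[i] * sd[j], 1e-300))
    if structure.error_model in ("proportional", "combined"):
        out.append(state.err_b)
    if structure.error_model in ("additive", "combined"):
        out.append(state.err_a)
    return np.array(out)


def _unpack(vec: np.ndarray, state: _State, structure: FitStructure) -> _State:
    st = state.copy()
    P = len(structure.param_names)
    R = len(structure.random_names)
    k = 0
    st.mu = np.log(np.maximum(vec[:P], 1e-300))
    k = P
    if structure.estimate_exponents:
        rand_j = [structure.param_names.index(p) for p in structure.random_names]
        st.expo = state.expo.copy()
        st.expo[rand_j] = vec[k : k + R]
        k += R
    sd = np.maximum(vec[k : k + R], 1e-10)
    k += R
    omega = np.diag(sd**2)
    for i, j in structure.corr_pairs():
        omega[i, j] = omega[j, i] = np.clip(vec[k], -0.99, 0.99) * sd[i] * sd[j]
        k += 1
    st.omega = omega
    if structure.error_model in ("proportional", "combined"):
        st.err_b = max(vec[k], 1e-10)
        k += 1
    if structure.error_model in ("additive", "combined"):
        st.err_a = max(vec[k], 1e-10)
        k += 1
    return st


def _standard_errors(data, structure, state, etas, covs, z):
    """SEs via numeric Hessian of the fixed-draw importance-sampled -2LL."""
    x0 = _pack(state, structure)
    n = x0.size

    def f(vec):
        st = _unpack(vec, state, structure)
        logw = _is_logweights(data, structure, st, etas, covs, z)
        logm = special.logsumexp(logw, axis=1) - np.log(z.shape[1])
        return float(-2.0 * logm.sum())

    h = 5e-3 * np.maximum(np.abs(x0), 0.05)
    H = np.zeros((n, n))
    f0 = f(x0)
    fp = np.zeros(n)
    fm = np.zeros(n)
    for a in range(n):
        ea = np.zeros(n); ea[a] = h[a]
        fp[a], fm[a] = f(x0 + ea), f(x0 - ea)
        H[a, a] = (fp[a] - 2 * f0 + fm[a]) / h[a] ** 2
    for a in range(n):
        ea = np.zeros(n); ea[a] = h[a]
        for b in range(a + 1, n):
            eb = np.zeros(n); eb[b] = h[b]
            H[a, b] = H[b, a] = (
                f(x0 + ea + eb) - f(x0 + ea - eb) - f(x0 - ea + eb) + f(x0 - ea - eb)
            ) / (4 * h[a] * h[b])
    ok = True
    try:
        cov = 2.0 * np.linalg.inv(H)
        var = np.diag(cov)
        if np.any(var <= 0):
            ok = False
        se = np.sqrt(np.abs(var))
    except np.linalg.LinAlgError:
        ok = False
        se = np.full(n, np.nan)
    return dict(zip(_pack_names(structure), se)), ok


# ---------------------------------------------------------------------------
# public fit API

@dataclass
class FitResult:
    params: dict  # typical values (natural scale)
    exponents: dict
    omegas: dict  # IIV SDs (log scale)
    corr: dict  # estimated correlations, e.g. {("cl", "v1"): 0.7}
    error: dict  # {"b": ..., "a": ...}
    se: dict | None  # SEs keyed like _pack_names
    rse_percent: dict | None
    minus2ll: float
    minus2ll_mc_se: float
    aic: float
    bic: float
    shrinkage: dict  # % per random effect
    eta_hat: np.ndarray  # (S, R) empirical Bayes (MAP) etas
    n_params: int
    n_subjects: int
    converged: bool
    se_ok: bool
    structure: FitStructure
    trace: dict | None = None

    @property
    def estimates(self) -> PopulationModel | None:
        """The fit as a PopulationModel (two-compartment structures only)."""
        if self.structure.n_compartments != 2:
            return None
        rn = self.structure.random_names
        return PopulationModel(
            theta=PKParameters(**{p: self.params[p] for p in ("cl", "v1", "q", "v2")}),
            beta_cl=self.exponents["cl"],
            beta_v1=self.exponents["v1"],
            beta_q=self.exponents["q"],
            beta_v2=self.exponents["v2"],
            omega_cl=self.omegas.get("cl", 0.0),
            omega_v1=self.omegas.get("v1", 0.0),
            omega_q=self.omegas.get("q", 0.0),
            corr_cl_v1=self.corr.get(("cl", "v1"), 0.0),
            prop_error_b=self.error.get("b", 0.0),
            add_error=self.error.get("a", 0.0),
        )


def fit_population(
    dataset: Dataset,
    structure: FitStructure | None = None,
    init: PopulationModel | None = None,
    k1: int = 300,
    k2: int = 100,
    n_chains: int = 4,
    seed: int = 0,
    compute_se: bool = True,
    is_samples: int = 400,
    store_trace: bool = False,
) -> FitResult:
    """Fit the population model to a dataset by SAEM.

    ``k1``/``k2`` are the burn-in and smoothing iteration counts (step size
    1 then 1/k); ``n_chains`` MCMC chains per subject are run in the E-step.
    The final -2LL (MOFV) is recomputed by importance sampling with
    ``is_samples`` draws per subject; AIC = -2LL + 2p, BIC = -2LL + p ln S.
    """
    structure = structure or FitStructure()
    if dataset.n_subjects < 5:
        raise ConfigurationError("population fitting needs at least 5 subjects")
    if n_chains < 1:
        raise ConfigurationError("need at least one MCMC chain")
    data = _prepare(dataset)
    rng = np.random.default_rng(seed)
    state = _init_state(data, structure, init)
    state, converged, trace = _run_saem(data, structure, state, k1, k2, n_chains, rng, store_trace)

    etas, covs = _map_etas(data, structure, state)
    R = len(structure.random_names)
    z = rng.standard_normal((data.n_subjects, is_samples, R))
    m2ll, mc_se = _is_minus2ll(data, structure, state, etas, covs, z)
    p = structure.n_parameters()
    se = rse = None
    se_ok = False
    if compute_se:
        se, se_ok = _standard_errors(data, structure, state, etas, covs, z)
        vec = _pack(state, structure)
        rse = {
            name: 100.0 * se[name] / abs(v) if abs(v) > 1e-12 else np.nan
            for name, v in zip(_pack_names(structure), vec)
        }

    sd = np.sqrt(np.diag(state.omega))
    shrink = {}
    for r, pname in enumerate(structure.random_names):
        shrink[pname] = float(eta_shrinkage(etas[:, r], sd[r]))
    corr = {}
    for i, j in structure.corr_pairs():
        rn = structure.random_names
        corr[(rn[i], rn[j])] = float(state.omega[i, j] / max(sd[i] * sd[j], 1e-300))
    return FitResult(
        params={p_: float(np.exp(state.mu[j])) for j, p_ in enumerate(structure.param_names)},
        exponents={p_: float(state.expo[j]) for j, p_ in enumerate(structure.param_names)},
        omegas={p_: float(sd[r]) for r, p_ in enumerate(structure.random_names)},
        corr=corr,
        error={"b": state.err_b, "a": state.err_a},
        se=se,
        rse_percent=rse,
        minus2ll=m2ll,
        minus2ll_mc_se=mc_se,
        aic=m2ll + 2 * p,
        bic=m2ll + p * np.log(data.n_subjects),
        shrinkage=shrink,
        eta_hat=etas,
        n_params=p,
        n_subjects=data.n_subjects,
        converged=converged,
        se_ok=se_ok,
        structure=structure,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# model comparison, shrinkage, bootstrap, pcVPC

@dataclass(frozen=True)
class ModelComparison:
    delta_mofv: float  # reduced - full (positive favours the full model)
    df: int | None
    delta_aic: float
    delta_bic: float
    nested: bool
    significant_forward: bool | None  # 10.8 threshold (p < 0.001, 1 df)
    significant_backward: bool | None  # 6.67 threshold (p < 0.01, 1 df)


def _is_nested(red: FitStructure, full: FitStructure) -> bool:
    err_order = {"additive": {"additive", "combined"}, "proportional": {"proportional", "combined"},
                 "combined": {"combined"}}
    return (
        red.n_compartments <= full.n_compartments
        and full.error_model in err_order[red.error_model]
        and set(red.random_names) <= set(full.random_names)
    )


def compare_models(fit_reduced: FitResult, fit_full: FitResult, nested: bool | None = None) -> ModelComparison:
    """Likelihood-ratio/AIC/BIC comparison of two fitted models.

    The MOFV-drop thresholds mirror the model-building rules: 10.8
    (p < 0.001, 1 df) for forward/structural inclusion and 6.67 (p < 0.01,
    1 df) for backward elimination.  Non-nested pairs get AIC/BIC only.
    """
    if nested is None:
        nested = _is_nested(fit_reduced.structure, fit_full.structure)
    delta = fit_reduced.minus2ll - fit_full.minus2ll
    d_aic = fit_reduced.aic - fit_full.aic
    d_bic = fit_reduced.bic - fit_full.bic
    if not nested:
        return ModelComparison(delta, None, d_aic, d_bic, False, None, None)
    df = fit_full.n_params - fit_reduced.n_params
    if df < 1:
        raise ConfigurationError("full model must have more parameters than the reduced one")
    return ModelComparison(delta, df, d_aic, d_bic, True, delta > 10.8, delta > 6.67)


def eta_shrinkage(eta_hats, omega):
    """Eta-shrinkage in percent: 100 * (1 - Var(eta_hat) / omega**2)."""
    eta_hats = np.asarray(eta_hats, dtype=float)
    if eta_hats.ndim == 1:
        eta_hats = eta_hats[:, None]
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if eta_hats.shape[0] < 2:
        raise ValueError("shrinkage needs at least 2 subjects")
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    out = 100.0 * (1.0 - np.var(eta_hats, axis=0, ddof=1) / omega**2)
    return float(out[0]) if out.size == 1 else out


@dataclass
class BootstrapResult:
    median: dict
    ci5: dict
    ci95: dict
    n_success: int
    n_failed: int
    samples: dict  # name -> np.ndarray of replicate estimates


def bootstrap(
    dataset: Dataset,
    n_reps: int,
    seed: int = 0,
    structure: FitStructure | None = None,
    init: PopulationModel | None = None,
    fit_kwargs: dict | None = None,
) -> BootstrapResult:
    """Subject-level nonparametric bootstrap of the population fit.

    Each replicate resamples subjects with replacement and refits; failed
    replicates are dropped and counted (> 50 % failures aborts).
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    kw = dict(k1=120, k2=60, compute_se=False, is_samples=100)
    kw.update(fit_kwargs or {})
    rows = []
    n_failed = 0
    for rep in range(n_reps):
        idx = rng.integers(0, dataset.n_subjects, size=dataset.n_subjects)
        subs = []
        for pos, i in enumerate(idx):
            s = dataset.subjects[i]
            subs.append(replace_subject_id(s, f"bs{rep}-{pos}"))
        ds = Dataset(subs, dict(dataset.meta))
        try:
            fit = fit_population(ds, structure=structure, init=init,
                                 seed=int(rng.integers(0, 2**31 - 1)), **kw)
            row = {f"theta_{k}": v for k, v in fit.params.items()}
            row.update({f"omega_{k}": v for k, v in fit.omegas.items()})
            row.update({f"corr_{a}_{b}": v for (a, b), v in fit.corr.items()})
            row.update({"b": fit.error["b"], "a": fit.error["a"]})
            rows.append(row)
        except (EstimationError, ConfigurationError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > 0.5 * n_reps:
        raise EstimationError(f"{n_failed}/{n_reps} bootstrap replicates failed")
    names = sorted(rows[0]) if rows else []
    samples = {k: np.array([r[k] for r in rows]) for k in names}
    return BootstrapResult(
        median={k: float(np.percentile(v, 50)) for k, v in samples.items()},
        ci5={k: float(np.percentile(v, 5)) for k, v in samples.items()},
        ci95={k: float(np.percentile(v, 95)) for k, v in samples.items()},
        n_success=len(rows),
        n_failed=n_failed,
        samples=samples,
    )


def replace_subject_id(subject, new_id):
    from dataclasses import replace as _dc_replace

    return _dc_replace(subject, id=new_id)


@dataclass
class VpcSummary:
    bin_edges: np.ndarray  # (n_bins + 1,)
    bin_median_time: np.ndarray  # (n_bins,)
    n_obs: np.ndarray  # (n_bins,)
    observed: np.ndarray  # (n_bins, 3) pc-observed 5/50/95 percentiles
    band50: np.ndarray  # (n_bins, 3, 2) 50 % interval of each simulated percentile
    band95: np.ndarray  # (n_bins, 3, 2) 95 % interval of each simulated percentile
    n_sim: int
    merged_bins: int = 0
    sim_percentiles: np.ndarray | None = None  # (n_bins, n_sim, 3) when kept

    def fraction_observed_in_95band(self) -> float:
        inside = (self.observed >= self.band95[:, :, 0]) & (self.observed <= self.band95[:, :, 1])
        return float(inside.mean())


def pcvpc(
    dataset: Dataset,
    pop: PopulationModel,
    n_sim: int = 1000,
    bins: Sequence[float] | None = None,
    seed: int = 0,
    keep_simulations: bool = False,
) -> VpcSummary:
    """Prediction-corrected visual predictive check.

    Observations and simulations are multiplied by (median population
    prediction in the bin) / (subject's population prediction at t), then
    5/50/95 percentiles of the corrected observations are compared with the
    50 % and 95 % intervals of the same percentiles over ``n_sim``
    simulated replicates of the original design.
    """
    if n_sim < 100:
        raise ConfigurationError("pcVPC needs at least 100 simulations")
    rng = np.random.default_rng(seed)
    subj_idx, t_rec, y_rec, pred_rec = [], [], [], []
    for i, s in enumerate(dataset.subjects):
        p_typ = pkmodel.individual_parameters(pop, s.bodyweight)
        for r in s.observed():
            subj_idx.append(i)
            t_rec.append(r.time)
            y_rec.append(r.conc)
            pred_rec.append(
                pkmodel.concentration(p_typ, s.regimen.total_dose, s.regimen.t_inf, r.time)
            )
    subj_idx = np.array(subj_idx)
    t_rec, y_rec, pred_rec = map(np.array, (t_rec, y_rec, pred_rec))
    if t_rec.size == 0:
        raise ConfigurationError("no usable observations")

    if bins is None:
        uniq = np.unique(np.round(t_rec, 6))
        if uniq.size <= 12:
            edges = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1.0]])
        else:
            edges = np.unique(np.quantile(t_rec, np.linspace(0, 1, 9)))
            edges[0], edges[-1] = 0.0, edges[-1] + 1.0
    else:
        edges = np.asarray(bins, dtype=float)
    bin_of = np.clip(np.digitize(t_rec, edges) - 1, 0, len(edges) - 2)

    # merge empty bins with their left neighbour
    merged = 0
    counts = np.bincount(bin_of, minlength=len(edges) - 1)
    while np.any(counts == 0) and len(edges) > 2:
        empty = int(np.where(counts == 0)[0][0])
        edges = np.delete(edges, max(empty, 1))
        bin_of = np.clip(np.digitize(t_rec, edges) - 1, 0, len(edges) - 2)
        counts = np.bincount(bin_of, minlength=len(edges) - 1)
        merged += 1
    n_bins = len(edges) - 1

    pred_med = np.array([np.median(pred_rec[bin_of == b]) for b in range(n_bins)])
    factor = pred_med[bin_of] / np.maximum(pred_rec, 1e-300)
    pc_obs = y_rec * factor

    # simulate replicates of the design
    S = dataset.n_subjects
    etas = pkmodel._sample_eta_array(pop, n_sim * S, rng).reshape(n_sim, S, 3)
    bw = np.array([s.bodyweight for s in dataset.subjects])
    dose = np.array([s.regimen.total_dose for s in dataset.subjects])
    tinf = np.array([s.regimen.t_inf for s in dataset.subjects])
    w = bw / pop.ref_weight
    th = pop.theta
    cl = th.cl * w[None, :] ** pop.beta_cl * np.exp(etas[:, :, 0])
    v1 = th.v1 * w[None, :] ** pop.beta_v1 * np.exp(etas[:, :, 1])
    q = th.q * w[None, :] ** pop.beta_q * np.exp(etas[:, :, 2])
    v2 = th.v2 * w[None, :] ** pop.beta_v2 * np.ones_like(cl)
    f_sim = pkmodel._profile(
        cl[:, subj_idx], v1[:, subj_idx], q[:, subj_idx], v2[:, subj_idx],
        dose[subj_idx][None, :], tinf[subj_idx][None, :], t_rec[None, :],
    )
    eps = rng.normal(0.0, pop.prop_error_b, size=f_sim.shape)
    y_sim = np.maximum(f_sim * (1.0 + eps), 0.0)
    if pop.add_error > 0:
        y_sim = np.maximum(y_sim + rng.normal(0.0, pop.add_error, size=f_sim.shape), 0.0)
    pc_sim = y_sim * factor[None, :]

    qs = (5, 50, 95)
    observed = np.empty((n_bins, 3))
    band50 = np.empty((n_bins, 3, 2))
    band95 = np.empty((n_bins, 3, 2))
    bin_median_time = np.empty(n_bins)
    kept = np.empty((n_bins, n_sim, 3)) if keep_simulations else None
    for b in range(n_bins):
        m = bin_of == b
        bin_median_time[b] = np.median(t_rec[m])
        observed[b] = np.percentile(pc_obs[m], qs)
        sim_pct = np.percentile(pc_sim[:, m], qs, axis=1).T  # (n_sim, 3)
        if kept is not None:
            kept[b] = sim_pct
        band50[b, :, 0] = np.percentile(sim_pct, 25, axis=0)
        band50[b, :, 1] = np.percentile(sim_pct, 75, axis=0)
        band95[b, :, 0] = np.percentile(sim_pct, 2.5, axis=0)
        band95[b, :, 1] = np.percentile(sim_pct, 97.5, axis=0)
    return VpcSummary(
        bin_edges=edges,
        bin_median_time=bin_median_time,
        n_obs=counts,
        observed=observed,
        band50=band50,
        band95=band95,
        n_sim=n_sim,
        merged_bins=merged,
        sim_percentiles=kept,
    )


def plot_pcvpc(summary: VpcSummary, ax=None):
    """Plot a pcVPC summary (requires matplotlib; installed via the
    ``plot`` extra).  Observed 5/50/95 percentiles as lines over the
    simulated 50 % and 95 % interval bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    x = summary.bin_median_time
    for p in range(3):
        ax.fill_between(x, summary.band95[:, p, 0], summary.band95[:, p, 1],
                        color="0.75", alpha=0.5, linewidth=0)
        ax.fill_between(x, summary.band50[:, p, 0], summary.band50[:, p, 1],
                        color="0.55", alpha=0.5, linewidth=0)
        ax.plot(x, summary.observed[:, p], "k-", lw=1.5 if p == 1 else 1.0)
    ax.set_yscale("log")
    ax.set_xlabel("time after infusion start (h)")
    ax.set_ylabel("prediction-corrected concentration (mg/L)")
    return ax


def wald_covariate_test(fit: FitResult, param: str):
    """Wald z-test of the estimated allometric exponent of ``param``.

    Requires a fit with ``estimate_exponents=True`` and standard errors.
    Returns ``(z, p_value)`` for H0: exponent = 0 (no bodyweight effect).
    """
    from scipy import stats as _st

    if not fit.structure.estimate_exponents or fit.se is None:
        raise ConfigurationError("needs a fit with estimated exponents and SEs")
    key = f"beta_{param}"
    if key not in fit.se:
        raise KeyError(f"no estimated exponent for {param}")
    z = fit.exponents[param] / fit.se[key]
    return float(z), float(2.0 * _st.norm.sf(abs(z)))
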