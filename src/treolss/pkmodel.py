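"""Two-compartment intravenous-infusion pharmacokinetic model of treosulfan.

The structural model is a linear two-compartment disposition model with
zero-order (constant-rate) input into the central compartment.  Individual
parameters are log-normally distributed around allometrically scaled typical
values referenced to a 70 kg adult,

    theta_i = theta * (BW_i / 70)**beta * exp(eta_i),

with ``beta = 0.75`` for clearance, ``1`` for distribution volumes and ``0``
for the intercompartmental clearance Q (no bodyweight effect on Q in the
final model).  Residual variability is proportional,

    C_obs = C_pred * (1 + eps1),    eps1 ~ N(0, b**2).

Units are mg for dose, h for time, L for volumes and mg/L for
concentrations throughout.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import yaml

from .exceptions import ConfigurationError

__all__ = [
    "PKParameters",
    "PopulationModel",
    "RandomEffects",
    "MicroConstants",
    "final_model",
    "individual_parameters",
    "micro_constants",
    "concentration",
    "auc_from_clearance",
    "apply_residual_error",
    "simulate_observations",
    "sample_random_effects",
]

_PARAM_NAMES = ("cl", "v1", "q", "v2")


@dataclass(frozen=True)
class PKParameters:
    """Structural two-compartment parameters of one individual.

    Attributes
    ----------
    cl : float
        Total (elimination) clearance, L/h.
    v1 : float
        Central compartment volume, L.
    q : float
        Intercompartmental clearance, L/h (``0`` collapses to one compartment).
    v2 : float
        Peripheral compartment volume, L.
    """

    cl: float
    v1: float
    q: float
    v2: float

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v1 > 0 and self.v2 > 0):
            raise ValueError("cl, v1 and v2 must be strictly positive")
        if self.q < 0:
            raise ValueError("q must be non-negative")


@dataclass(frozen=True)
class RandomEffects:
    """Log-scale interindividual deviations (eta) for Cl, V1 and Q.

    V2 carries no interindividual variability in the final model, so its
    eta is identically zero and not represented.
    """

    eta_cl: float = 0.0
    eta_v1: float = 0.0
    eta_q: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("random effects must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.eta_cl, self.eta_v1, self.eta_q], dtype=float)


@dataclass(frozen=True)
class PopulationModel:
    """Population model: typical values, allometry, IIV and residual error.

    ``theta`` holds typical values referenced to ``ref_weight`` (70 kg).
    ``omega_*`` are standard deviations of the log-scale random effects;
    ``corr_cl_v1`` is the correlation between ``eta_cl`` and ``eta_v1``
    (the only non-zero off-diagonal element of the IIV covariance).
    ``prop_error_b`` is the proportional residual SD; ``add_error`` the
    additive residual SD in mg/L (0 in the final model).
    """

    theta: PKParameters
    beta_cl: float = 0.75
    beta_v1: float = 1.0
    beta_q: float = 0.0
    beta_v2: float = 1.0
    ref_weight: float = 70.0
    omega_cl: float = 0.0
    omega_v1: float = 0.0
    omega_q: float = 0.0
    corr_cl_v1: float = 0.0
    prop_error_b: float = 0.0
    add_error: float = 0.0

    def __post_init__(self) -> None:
        for name in ("omega_cl", "omega_v1", "omega_q", "prop_error_b", "add_error"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if abs(self.corr_cl_v1) > 1:
            raise ConfigurationError("corr_cl_v1 must lie in [-1, 1]")
        for name in ("beta_cl", "beta_v1", "beta_q", "beta_v2"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if self.ref_weight <= 0:
            raise ConfigurationError("ref_weight must be positive")
        # implied 2x2 (Cl, V1) covariance must be PSD; |corr| <= 1 guarantees it
        np.linalg.cholesky(self.omega_matrix() + 1e-12 * np.eye(3))

    def omega_matrix(self) -> np.ndarray:
        """3x3 IIV covariance for (eta_cl, eta_v1, eta_q)."""
        cov = np.diag([self.omega_cl**2, self.omega_v1**2, self.omega_q**2]).astype(float)
        cov[0, 1] = cov[1, 0] = self.corr_cl_v1 * self.omega_cl * self.omega_v1
        return cov

    def betas(self) -> np.ndarray:
        return np.array([self.beta_cl, self.beta_v1, self.beta_q, self.beta_v2])

    def to_dict(self) -> dict:
        d = {
            "theta": {n: getattr(self.theta, n) for n in _PARAM_NAMES},
            "beta": {
                "cl": self.beta_cl,
                "v1": self.beta_v1,
                "q": self.beta_q,
                "v2": self.beta_v2,
            },
            "ref_weight": self.ref_weight,
            "omega": {"cl": self.omega_cl, "v1": self.omega_v1, "q": self.omega_q},
            "corr_cl_v1": self.corr_cl_v1,
            "prop_error_b": self.prop_error_b,
            "add_error": self.add_error,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        theta = PKParameters(**{k: float(v) for k, v in d["theta"].items()})
        beta = d.get("beta", {})
        omega = d.get("omega", {})
        return cls(
            theta=theta,
            beta_cl=float(beta.get("cl", 0.75)),
            beta_v1=float(beta.get("v1", 1.0)),
            beta_q=float(beta.get("q", 0.0)),
            beta_v2=float(beta.get("v2", 1.0)),
            ref_weight=float(d.get("ref_weight", 70.0)),
            omega_cl=float(omega.get("cl", 0.0)),
            omega_v1=float(omega.get("v1", 0.0)),
            omega_q=float(omega.get("q", 0.0)),
            corr_cl_v1=float(d.get("corr_cl_v1", 0.0)),
            prop_error_b=float(d.get("prop_error_b", 0.0)),
            add_error=float(d.get("add_error", 0.0)),
        )


def final_model(path: str | None = None) -> PopulationModel:
    """Load the packaged final population model (or a user YAML config).

    The packaged defaults are the final estimates of the pediatric
    treosulfan model: Cl 14.7 L/h/70 kg, V1 26.0 L/70 kg, Q 2.25 L/h,
    V2 9.93 L/70 kg, IIV 25.5/51.4/38.6 % with corr(eta_Cl, eta_V1) 0.714,
    proportional error 0.188.
    """
    if path is None:
        ref = importlib.resources.files("treolss").joinpath("data/final_model.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return PopulationModel.from_dict(yaml.safe_load(text))


def individual_parameters(
    pop: PopulationModel, bodyweight: float, eta: RandomEffects | None = None
) -> PKParameters:
    """Individual parameters from typical values, allometry and random effects.

    theta_i = theta * (BW/ref)**beta * exp(eta); eta_V2 is fixed at 0.
    """
    if bodyweight <= 0:
        raise ValueError("bodyweight must be positive")
    if eta is None:
        eta = RandomEffects()
    w = bodyweight / pop.ref_weight
    t = pop.theta
    return PKParameters(
        cl=t.cl * w**pop.beta_cl * np.exp(eta.eta_cl),
        v1=t.v1 * w**pop.beta_v1 * np.exp(eta.eta_v1),
        q=t.q * w**pop.beta_q * np.exp(eta.eta_q),
        v2=t.v2 * w**pop.beta_v2,
    )


class MicroConstants(NamedTuple):
    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float


def micro_constants(p: PKParameters) -> MicroConstants:
    """Micro rate constants and disposition exponents of the model.

    ``alpha`` and ``beta`` are the (fast, slow) roots of
    ``s**2 - (k10 + k12 + k21) s + k10 k21``; ``beta`` is the terminal
    elimination rate constant (lambda_z of a rich profile).
    """
    k10 = p.cl / p.v1
    k12 = p.q / p.v1
    k21 = p.q / p.v2
    s = k10 + k12 + k21
    disc = np.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return MicroConstants(k10, k12, k21, alpha, beta)


def _profile(cl, v1, q, v2, dose, t_inf, t):
    """Vectorised closed-form concentration; arrays broadcast.

    Handles the one-compartment limit q == 0 exactly.  All parameter
    arguments must be strictly positive except q >= 0.
    """
    cl, v1, q, v2, dose, t_inf, t = np.broadcast_arrays(
        *[np.asarray(x, dtype=float) for x in (cl, v1, q, v2, dose, t_inf, t)]
    )
    rate = dose / t_inf
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    # guard against the (measure-zero) repeated-root case
    disc = np.maximum(disc, 1e-10 * s)
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)

    tau = np.minimum(t, t_inf)  # time spent infusing
    te = np.maximum(t - t_inf, 0.0)  # time since end of infusion

    with np.errstate(divide="ignore", invalid="ignore"):
        a_coef = (alpha - k21) / (alpha - beta)
        b_coef = (k21 - beta) / (alpha - beta)
        two = (rate / v1) * (
            (a_coef / alpha) * (1.0 - np.exp(-alpha * tau)) * np.exp(-alpha * te)
            + (b_coef / beta) * (1.0 - np.exp(-beta * tau)) * np.exp(-beta * te)
        )
    one = (rate / cl) * (1.0 - np.exp(-k10 * tau)) * np.exp(-k10 * te)
    out = np.where(q <= 0.0, one, two)
    return np.where(t <= 0.0, 0.0, out)


def concentration(p: PKParameters, dose: float, t_inf: float, t):
    """Plasma concentration (mg/L) at time(s) ``t`` hours after infusion start.

    A dose of ``dose`` mg is infused at constant rate over ``t_inf`` hours.
    ``t`` may be a scalar or array; negative times are a domain error.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if t_inf <= 0:
        raise ValueError("infusion duration must be positive")
    out = _profile(p.cl, p.v1, p.q, p.v2, dose, t_inf, t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def auc_from_clearance(dose: float, cl: float) -> float:
    """AUC from 0 to infinity of a linear system: dose / clearance (mg*h/L)."""
    if cl <= 0:
        raise ValueError("clearance must be positive")
    return dose / cl


def apply_residual_error(c_pred, pop: PopulationModel, eps1, eps2=None):
    """Apply the residual error model to noise-free predictions.

    ``eps1`` (and optionally ``eps2``) are the realised noise draws, e.g.
    from N(0, b**2).  The final model is proportional-only (eps2 == 0).
    Negative results are truncated at 0 (a < 0.01 % event at b = 0.188).
    """
    c_pred = np.asarray(c_pred, dtype=float)
    if np.any(c_pred < 0):
        raise ValueError("predicted concentrations must be non-negative")
    eps2 = 0.0 if eps2 is None else eps2
    obs = c_pred * (1.0 + np.asarray(eps1, dtype=float)) + eps2
    return np.maximum(obs, 0.0)


def simulate_observations(c_pred, pop: PopulationModel, rng: np.random.Generator):
    """Draw observed concentrations under the population residual-error model.

    Returns ``(c_obs, truncated)`` where ``truncated`` flags values clipped
    to zero after noise.
    """
    c_pred = np.asarray(c_pred, dtype=float)
    eps1 = rng.normal(0.0, pop.prop_error_b, size=c_pred.shape)
    eps2 = rng.normal(0.0, pop.add_error, size=c_pred.shape) if pop.add_error > 0 else 0.0
    raw = c_pred * (1.0 + eps1) + eps2
    return np.maximum(raw, 0.0), raw < 0


def _sample_eta_array(pop: PopulationModel, n: int, rng: np.random.Generator) -> np.ndarray:
    cov = pop.omega_matrix()
    try:
        chol = np.linalg.cholesky(cov + 1e-14 * np.eye(3))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by invariants
        raise ConfigurationError("IIV covariance is not positive semi-definite") from exc
    z = rng.standard_normal((n, 3))
    out = z @ chol.T
    out[:, cov.diagonal() == 0] = 0.0
    return out


def sample_random_effects(
    pop: PopulationModel, n: int, seed: int | np.random.Generator | None = None
) -> list[RandomEffects]:
    """Draw ``n`` eta vectors from the multivariate-normal IIV distribution."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = _sample_eta_array(pop, n, rng)
    return [RandomEffects(*row) for row in arr]
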