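"""Virtual pediatric cohort simulator.

Generates the cohorts the limited-sampling-strategy study assumes: 100
virtual patients per dosing group with bodyweights drawn from a truncated
normal emulating the study population (mean 26.9 kg, SD 15.7 kg, truncated
to 5-55 kg), body surface area from bodyweight, BSA-based dosing (10, 12 or
14 g/m2 as 1 h or 2 h infusions), two-compartment profiles with log-normal
IIV, proportional observation noise, and LOQ censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import pkmodel
from .exceptions import ConfigurationError
from .pkmodel import PKParameters, PopulationModel, RandomEffects

__all__ = [
    "CANDIDATE_TIMES",
    "LOQ_DEFAULT",
    "DoseRegimen",
    "ConcentrationRecord",
    "Subject",
    "Dataset",
    "sample_bodyweights",
    "bsa_from_weight",
    "simulate_group",
    "emulate_study_dataset",
]

#: Candidate sampling grid inspected for limited sampling strategies (h).
CANDIDATE_TIMES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0, 8.0, 12.0)

#: Lower limit of quantification, mg/L (0.2 umol/L x 278.3 g/mol).
LOQ_DEFAULT = 0.0556

_ALLOWED_DOSES = (10.0, 12.0, 14.0)
_SPARSE_DESIGN = (0.5, 1.0, 3.0, 4.0, 6.0, 8.0)
_RICH_DESIGN = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 8.0, 12.0)


@dataclass(frozen=True)
class DoseRegimen:
    """Dosing regimen: BSA-normalised dose, infusion length, total dose (mg)."""

    dose_per_bsa: float  # g/m2
    t_inf: float  # h
    total_dose: float  # mg

    def __post_init__(self) -> None:
        if self.dose_per_bsa <= 0 or self.t_inf <= 0 or self.total_dose <= 0:
            raise ValueError("regimen fields must be positive")

    @classmethod
    def for_bsa(cls, dose_per_bsa: float, t_inf: float, bsa: float) -> "DoseRegimen":
        if dose_per_bsa not in _ALLOWED_DOSES:
            raise ConfigurationError(f"dose_per_bsa must be one of {_ALLOWED_DOSES} g/m2")
        if t_inf not in (1.0, 2.0):
            raise ConfigurationError("infusion length must be 1 or 2 h")
        return cls(dose_per_bsa, t_inf, dose_per_bsa * bsa * 1000.0)


@dataclass(frozen=True)
class ConcentrationRecord:
    time: float  # h after infusion start
    conc: float  # mg/L
    blq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be non-negative")
        if self.conc < 0:
            raise ValueError("concentration must be non-negative")


@dataclass
class Subject:
    """One virtual (or observed) patient with dosing and sampled concentrations."""

    id: str
    bodyweight: float
    bsa: float
    regimen: DoseRegimen
    records: list[ConcentrationRecord] = field(default_factory=list)
    eta: RandomEffects | None = None
    true_params: PKParameters | None = None
    true_auc: float | None = None

    def __post_init__(self) -> None:
        if self.bsa <= 0:
            raise ValueError("bsa must be positive")
        times = [r.time for r in self.records]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("record times must be strictly increasing")

    def observed(self) -> list[ConcentrationRecord]:
        """Records retained for analysis (BLQ records removed)."""
        return [r for r in self.records if not r.blq]

    def conc_at(self, times) -> np.ndarray:
        """Non-BLQ concentrations at exactly the requested times (KeyError if absent)."""
        lookup = {round(r.time, 9): r.conc for r in self.observed()}
        try:
            return np.array([lookup[round(float(t), 9)] for t in times])
        except KeyError as exc:
            raise KeyError(f"subject {self.id} has no usable record at t={exc.args[0]} h") from exc


@dataclass
class Dataset:
    subjects: list[Subject]
    meta: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def n_records(self, include_blq: bool = True) -> int:
        return sum(len(s.records if include_blq else s.observed()) for s in self.subjects)

    def subset(self, ids) -> "Dataset":
        ids = set(ids)
        return Dataset([s for s in self.subjects if s.id in ids], dict(self.meta))


def sample_bodyweights(
    n: int,
    mean: float = 26.9,
    sd: float = 15.7,
    lower: float = 5.0,
    upper: float = 55.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw bodyweights (kg) from a normal truncated to [lower, upper].

    Defaults emulate the study population: mean 26.9, SD 15.7, bounds 5-55 kg
    bracketing the realized 5.8-53.9 kg range of the simulated cohort.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if not (0 < lower < upper):
        raise ConfigurationError("bounds must satisfy 0 < lower < upper")
    if not (lower <= mean <= upper):
        raise ConfigurationError("mean must lie within the truncation bounds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sd == 0:
        return np.full(n, float(mean))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def bsa_from_weight(bodyweight: float):
    """Body surface area (m2) from bodyweight (kg).

    Uses the weight-only power formula BSA[cm2] = 4.688 * W[g]**(0.8168 -
    0.0154 log10 W[g]), the relation used to assign BSA-based doses to the
    virtual patients.  Accepts scalars or arrays.
    """
    w = np.asarray(bodyweight, dtype=float)
    if np.any(w <= 0):
        raise ValueError("bodyweight must be positive")
    grams = w * 1000.0
    bsa_cm2 = 4.688 * grams ** (0.8168 - 0.0154 * np.log10(grams))
    out = bsa_cm2 / 1e4
    return float(out) if np.isscalar(bodyweight) else out


def _simulate_subject(
    pop: PopulationModel,
    sid: str,
    bodyweight: float,
    dose_per_bsa: float,
    t_inf: float,
    design,
    loq: float,
    eta: RandomEffects,
    rng: np.random.Generator,
    residual_error: bool = True,
) -> Subject:
    bsa = bsa_from_weight(bodyweight)
    regimen = DoseRegimen.for_bsa(dose_per_bsa, t_inf, bsa)
    params = pkmodel.individual_parameters(pop, bodyweight, eta)
    times = np.asarray(design, dtype=float)
    c_pred = pkmodel.concentration(params, regimen.total_dose, regimen.t_inf, times)
    if residual_error:
        c_obs, _ = pkmodel.simulate_observations(c_pred, pop, rng)
    else:
        c_obs = c_pred
    records = [
        ConcentrationRecord(time=float(t), conc=float(c), blq=bool(c < loq))
        for t, c in zip(times, c_obs)
    ]
    return Subject(
        id=sid,
        bodyweight=float(bodyweight),
        bsa=float(bsa),
        regimen=regimen,
        records=records,
        eta=eta,
        true_params=params,
        true_auc=regimen.total_dose / params.cl,
    )


def simulate_group(
    pop: PopulationModel,
    dose_per_bsa: float,
    t_inf: float,
    n: int,
    design=CANDIDATE_TIMES,
    loq: float = LOQ_DEFAULT,
    seed: int | None = None,
    id_prefix: str | None = None,
    residual_error: bool = True,
) -> Dataset:
    """Simulate one dosing group of ``n`` virtual patients.

    Each subject receives all ``design`` times (LSS subsetting happens
    downstream); observations below ``loq`` are flagged BLQ and excluded
    from analysis by consumers.  With ``residual_error=False`` the records
    are the individual *predicted* concentrations (IIV only) - the form in
    which the virtual cohorts enter limited-sampling development.
    """
    design = tuple(float(t) for t in design)
    if len(design) == 0:
        raise ConfigurationError("sampling design must be non-empty")
    if any(t < 0 or t > 24 for t in design):
        raise ConfigurationError("design times must lie within [0, 24] h")
    rng = np.random.default_rng(seed)
    weights = sample_bodyweights(n, seed=rng)
    etas = pkmodel.sample_random_effects(pop, n, rng)
    prefix = id_prefix or f"{dose_per_bsa:g}g-{t_inf:g}h"
    subjects = [
        _simulate_subject(pop, f"{prefix}-{i + 1:03d}", w, dose_per_bsa, t_inf, design, loq, e,
                          rng, residual_error)
        for i, (w, e) in enumerate(zip(weights, etas))
    ]
    meta = {
        "design": design,
        "dose_per_bsa": dose_per_bsa,
        "t_inf": t_inf,
        "loq": loq,
        "seed": seed,
        "residual_error": residual_error,
    }
    return Dataset(subjects, meta)


def emulate_study_dataset(
    pop: PopulationModel, seed: int | None = None, loq: float = LOQ_DEFAULT
) -> Dataset:
    """A 15-subject dataset emulating the original study's mixed design.

    Dosing groups 1 x 10 g/m2-1 h, 4 x 12-1 h, 4 x 12-2 h, 6 x 14-2 h; the
    first 7 subjects follow the sparse 6-sample schedule, the remaining 8
    the rich 10-sample schedule (102 records before BLQ filtering).
    """
    rng = np.random.default_rng(seed)
    groups = [(10.0, 1.0, 1), (12.0, 1.0, 4), (12.0, 2.0, 4), (14.0, 2.0, 6)]
    weights = sample_bodyweights(15, seed=rng)
    etas = pkmodel.sample_random_effects(pop, 15, rng)
    subjects = []
    idx = 0
    for dose_per_bsa, t_inf, count in groups:
        for _ in range(count):
            design = _SPARSE_DESIGN if idx < 7 else _RICH_DESIGN
            subjects.append(
                _simulate_subject(
                    pop,
                    f"study-{idx + 1:02d}",
                    weights[idx],
                    dose_per_bsa,
                    t_inf,
                    design,
                    loq,
                    etas[idx],
                    rng,
                )
            )
            idx += 1
    return Dataset(subjects, {"design": "study-emulation", "loq": loq, "seed": seed})
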