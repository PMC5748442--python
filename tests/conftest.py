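from dataclasses import replace

import pytest

import treolss as t


@pytest.fixture(scope="session")
def pop() -> t.PopulationModel:
    """The packaged final population model (Cl 14.7, V1 26.0, Q 2.25, V2 9.93...)."""
    return t.final_model()


@pytest.fixture(scope="session")
def typical(pop) -> t.PKParameters:
    return pop.theta


@pytest.fixture(scope="session")
def noiseless_pop(pop) -> t.PopulationModel:
    """Final model with the residual error switched off (IIV retained)."""
    return replace(pop, prop_error_b=0.0)


@pytest.fixture(scope="session")
def deterministic_pop(pop) -> t.PopulationModel:
    """Final model with neither IIV nor residual error."""
    return replace(pop, prop_error_b=0.0, omega_cl=0.0, omega_v1=0.0, omega_q=0.0,
                   corr_cl_v1=0.0)


@pytest.fixture(scope="session")
def group_12g_2h(pop) -> t.Dataset:
    """100 virtual patients, 12 g/m2 over 2 h, prediction-level profiles."""
    return t.simulate_group(pop, 12.0, 2.0, 100, seed=11, residual_error=False)


@pytest.fixture(scope="session")
def rich_noisy_cohort(pop) -> t.Dataset:
    """100 virtual patients with IIV and proportional noise on the full grid."""
    return t.simulate_group(pop, 12.0, 2.0, 100, seed=42, residual_error=True)
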