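import warnings

import pytest
from hypothesis import HealthCheck, settings

from extempore_be import datasets
from extempore_be.absorption import SimulationConfig, default_fasted_physiology
from extempore_be.substances import DrugSubstance, Pka

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# the amlodipine record intentionally carries a half-life inconsistent with
# CL/Vc; the derivation warning is expected throughout the suite
warnings.filterwarnings(
    "ignore", message=".*half-life.*inconsistent.*", category=UserWarning
)


@pytest.fixture(scope="session")
def aml() -> DrugSubstance:
    return datasets.load_drug("amlodipine")


@pytest.fixture(scope="session")
def val() -> DrugSubstance:
    return datasets.load_drug("valsartan")


@pytest.fixture(scope="session")
def physiology():
    return default_fasted_physiology()


@pytest.fixture()
def light_drug() -> DrugSubstance:
    """Small, fast-to-simulate neutral compound for property tests."""
    return DrugSubstance(
        name="probe",
        molecular_weight_g_mol=300.0,
        log_d=1.0,
        pka_values=[],
        ref_solubility_mg_ml=1.0,
        ref_solubility_ph=7.0,
        peff_cm_s=2.0e-4,
        peff_assay="human",
        dose_mg=10.0,
        diffusion_coefficient_cm2_s=5.0e-6,
        vc_l_kg=0.5,
        clearance_l_h=3.0,
        body_weight_kg=70.0,
        simulation_time_h=24.0,
    )


@pytest.fixture()
def light_config() -> SimulationConfig:
    return SimulationConfig(
        duration_h=24.0, output_step_h=0.1, rtol=1e-7, atol=1e-9
    )
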