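import pytest
from hypothesis import HealthCheck, settings

from platestat import (
    ControllerConfig,
    ExperimentConfig,
    MeasurementConfig,
    StrainParams,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def noise_free() -> MeasurementConfig:
    return MeasurementConfig(mult_cv=0.0, add_sd=0.0)


@pytest.fixture
def three_strain_plate() -> list[StrainParams]:
    """Three E. coli strains with the observed growth rates and the starting
    densities implied by the second-measurement ODs of the reference run."""
    return [
        StrainParams("TG1", mu_max=1.37, lag_time=0.0, x0=0.06),
        StrainParams("TG90", mu_max=1.28, lag_time=0.0, x0=0.056),
        StrainParams("BW25113", mu_max=1.32, lag_time=0.0, x0=0.088),
    ]


@pytest.fixture
def noise_free_cfg(three_strain_plate, noise_free) -> ExperimentConfig:
    return ExperimentConfig(
        plate=three_strain_plate,
        measurement=noise_free,
        controller=ControllerConfig(),
        seed=0,
    )
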