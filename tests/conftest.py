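import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "drpanel",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("drpanel")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def null_panel_n5():
    """One 40-strain, 5-per-arm experiment with no true strain variation."""
    from drpanel import DesignSpec, EffectModel, simulate_experiment

    return simulate_experiment(
        DesignSpec(n_strains=40, n_per_strain_per_diet=5),
        EffectModel(mu=-0.5, sigma_delta=0.0),
        np.random.default_rng(777),
    )


@pytest.fixture(scope="session")
def variable_panel_n10():
    """A 40-strain, 10-per-arm experiment with genuine strain variation."""
    from drpanel import DesignSpec, EffectModel, simulate_experiment

    return simulate_experiment(
        DesignSpec(n_strains=40, n_per_strain_per_diet=10),
        EffectModel(mu=-0.5, sigma_delta=0.5),
        np.random.default_rng(888),
    )
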