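import pytest
from hypothesis import HealthCheck, settings

from t1rho_infarct import PhantomConfig, generate_phantom, simulate_tsl_series

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """Coarse 3-slice annulus with a 90° transmural infarct sector."""
    return PhantomConfig(
        matrix=(96, 96), pixel_spacing=1.0, n_slices=3,
        epi_radius=30.0, endo_radius=20.0,
        infarct_center_angle=45.0, infarct_angular_extent=90.0,
        supersample_factor=4, noise_sigma=2.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_phantom(small_config)


@pytest.fixture(scope="session")
def small_series(small_truth):
    return simulate_tsl_series(small_truth)


@pytest.fixture(scope="session")
def crisp_config(small_config):
    """Same geometry without partial volume (supersample 1, crisp labels)."""
    import dataclasses
    return dataclasses.replace(small_config, supersample_factor=1,
                               noise_sigma=0.0)


@pytest.fixture(scope="session")
def crisp_truth(crisp_config):
    return generate_phantom(crisp_config)
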