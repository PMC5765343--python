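import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spermbeat import AcquisitionConfig, FlagellumModel, generate_video

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down acquisition for fast unit tests."""
    return AcquisitionConfig(height_px=64, width_px=96, fps=300.0, n_frames=150)


@pytest.fixture(scope="session")
def small_model():
    return FlagellumModel(
        length_um=25.0,
        amplitude_um=3.0,
        beat_frequency_hz=12.0,
        wavelength_um=20.0,
        head_position_px=(32.0, 10.0),
    )


@pytest.fixture(scope="session")
def small_video(small_model, small_config):
    return generate_video(small_model, small_config)


@pytest.fixture(scope="session")
def static_video(small_config):
    """Motionless flagellum (amplitude 0), noise-free."""
    model = FlagellumModel(
        length_um=25.0,
        amplitude_um=0.0,
        beat_frequency_hz=12.0,
        wavelength_um=20.0,
        head_position_px=(32.0, 10.0),
    )
    return generate_video(model, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
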