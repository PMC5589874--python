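import numpy as np
import pytest

from qpraman.synthetic import (
    CellPhantom,
    SimulationConfig,
    default_spectral_groups,
    make_phase_map,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """256² field: large enough for <1 % discretisation error, fast to FFT."""
    return SimulationConfig(seed=7, image_size=256, pixel_size=0.1)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture
def smooth_phantom(small_config) -> CellPhantom:
    fov = small_config.field_of_view
    return CellPhantom(center=(fov / 2, fov / 2), radius=8.0, peak_phase=1.0,
                       profile="gaussian_cap")


@pytest.fixture
def disk_phantom(small_config) -> CellPhantom:
    fov = small_config.field_of_view
    return CellPhantom(center=(fov / 2, fov / 2), radius=8.0, peak_phase=1.0,
                       profile="uniform_disk")


@pytest.fixture(scope="session")
def wavenumber_axis() -> np.ndarray:
    return np.arange(400.0, 2001.0, 1.0)


@pytest.fixture(scope="session")
def spectral_groups():
    return default_spectral_groups()
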