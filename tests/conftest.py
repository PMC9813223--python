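import pytest
from hypothesis import settings

from lissavol import ClockConfig, Geometry, ScanConfig

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cfg() -> ScanConfig:
    """Full working configuration: 80 MHz / 456 kHz / 7834 Hz, 343 um FOV,
    256 x 256 x 80 grid, bidirectional duty 0.65 -> 30.6 vps."""
    return ScanConfig()


@pytest.fixture(scope="session")
def small_cfg() -> ScanConfig:
    """Dynamic-imaging configuration (80 x 80 um lateral FOV) with a reduced
    pulse rate so full-pipeline tests stay fast; rates are unchanged."""
    return ScanConfig(clocks=ClockConfig(f_rep=8e6), geometry=Geometry(fov_x=80.0, fov_y=80.0))


@pytest.fixture(scope="session")
def tiny_cfg() -> ScanConfig:
    """Few-line scan (8 y lines) for cheap end-to-end IO/CLI tests."""
    return ScanConfig(
        clocks=ClockConfig(f_rep=8e6),
        geometry=Geometry(fov_x=80.0, fov_y=80.0, n_x=64, n_y=8, n_z=40),
    )
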