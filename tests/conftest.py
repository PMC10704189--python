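import pytest

from patiploc.geometry import ImagingConfig, TransducerSpec


@pytest.fixture(scope="session")
def spec() -> TransducerSpec:
    return TransducerSpec()


@pytest.fixture(scope="session")
def config() -> ImagingConfig:
    return ImagingConfig()


@pytest.fixture(scope="session")
def small_spec() -> TransducerSpec:
    """Reduced array for brute-force oracles and fast end-to-end runs."""
    return TransducerSpec(n_elements=16, sampling_frequency_hz=8e6,
                          center_frequency_hz=1.5e6)


@pytest.fixture(scope="session")
def small_config() -> ImagingConfig:
    return ImagingConfig(depth_max_mm=40.0, scan_pixel_lateral_um=300.0,
                         processed_size=64)


@pytest.fixture(scope="session")
def template_bank(spec, config):
    """Default-configuration template bank, shared across the suite."""
    from patiploc.detector import build_template_bank
    return build_template_bank(spec, config)
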