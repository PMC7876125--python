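import pytest

from padsense.synth import SynthParams


@pytest.fixture
def params_clean():
    """Noise-free, ramp-free generator: responses are exact."""
    return SynthParams(noise_sd=0.0, illum_gradient=0.0, device_rsd=0.0)


@pytest.fixture
def params_noisy():
    """Reference study conditions (pixel noise SD 2, 2% illumination ramp)."""
    return SynthParams()
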