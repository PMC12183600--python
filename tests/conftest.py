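import pytest

import georquant as gq


@pytest.fixture(scope="session")
def library():
    """Full default library including lactic acid and the salt pseudo-peak."""
    return gq.default_library()


@pytest.fixture(scope="session")
def panel_library():
    """The eight validated analytes only."""
    return gq.default_library(include_extras=False)


@pytest.fixture(scope="session")
def zero_noise():
    return gq.ZERO_NOISE


@pytest.fixture()
def noise():
    return gq.NoiseModel(seed=42)


@pytest.fixture(scope="session")
def standard_sample():
    """Noise-free 8-analyte standard: 1 mM panel acids/carbonyls + 20 mM
    glycerol (inside its validated 16-40 mM range)."""
    sample = {n: 1.0 for n in gq.PANEL}
    sample["glycerol"] = 20.0
    return sample
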