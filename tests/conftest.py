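import pytest

from specdcm.cohort import baseline_vector
from specdcm.forward import default_frequency_grid, vector_to_model

TR = 1.97
N_VOLUMES = 255


@pytest.fixture(scope="session")
def freqs():
    """Analysis band matching a 255-volume run at TR = 1.97 s."""
    return default_frequency_grid(N_VOLUMES, TR)


@pytest.fixture(scope="session")
def baseline_model_3():
    """Population-baseline 3-node generative model."""
    return vector_to_model(baseline_vector(3), 3)
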