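import numpy as np
import pytest

from attract_choice import AttractionParams, ModelBConfig


@pytest.fixture
def hyper_params():
    """Hyperbolic attraction at the canonical illustrative values."""
    return AttractionParams(A=10.0, a=0.4, N_c=10.0)


@pytest.fixture
def symmetric_area_config():
    """Fixed-area scenario with both species identical (A=1, a=0.4, b=1)."""
    return ModelBConfig(
        p=0.0, b=1.0, total_area=1.0,
        params=AttractionParams(A_w=1.0, A_c=1.0, a_w=0.4, a_c=0.4),
    )


@pytest.fixture
def attractive_wild_config():
    """Fixed-area scenario with much more attractive wildflowers (A_w=10)."""
    return ModelBConfig(
        p=0.0, b=1.0, total_area=1.0,
        params=AttractionParams(A_w=10.0, A_c=1.0, a_w=0.4, a_c=0.4),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250917)
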