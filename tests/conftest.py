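import numpy as np
import pytest

from embedgrn.params import NodeParams, ToggleParams, TwoNodeParams


@pytest.fixture
def toggle_params() -> ToggleParams:
    return ToggleParams(basal=0.2, strength=4.0, hill=3.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def generic_twonode() -> TwoNodeParams:
    """A well-behaved parameter set with both axis equilibria present."""
    return TwoNodeParams(
        NodeParams(gain=4.0, self_sat=1.0, cross=2.0, deg=1.0),
        NodeParams(gain=3.0, self_sat=0.5, cross=1.5, deg=1.0),
    )
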