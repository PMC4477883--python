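import numpy as np
import pytest

from duolattice import (
    CouplingField,
    DuplexState,
    LatticeGeometry,
    PayoffParams,
    draw_coupling_field,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_state(
    upper,
    lower,
    b=1.05,
    K=0.1,
    A=0.5,
    scheme="symmetric",
    coupling_seed=7,
):
    """Build a DuplexState from explicit strategy arrays."""
    upper = np.asarray(upper, dtype=np.int8)
    lower = np.asarray(lower, dtype=np.int8)
    geometry = LatticeGeometry(upper.shape[0])
    field = draw_coupling_field(
        geometry, A, scheme, np.random.default_rng(coupling_seed)
    )
    return DuplexState(
        upper=upper,
        lower=lower,
        coupling=field,
        geometry=geometry,
        payoff=PayoffParams(b, K=K),
    )


def random_state(L, rng, **kwargs):
    upper = rng.integers(0, 2, size=(L, L), dtype=np.int8)
    lower = rng.integers(0, 2, size=(L, L), dtype=np.int8)
    return make_state(upper, lower, **kwargs)
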