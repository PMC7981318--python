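import numpy as np
import pytest
from hypothesis import settings

from ciliascreen import synthgen
from ciliascreen.plate import Role, build_layout

# property tests must behave identically on every run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_field():
    """A rendered mid-density field reused across detection tests."""
    spec = synthgen.FieldSpec(
        n_cells=50, ciliation_prob=0.5, multi_cilium_prob=0.05, seed=7
    )
    return spec, synthgen.render_field(spec)


@pytest.fixture(scope="session")
def toy_layout():
    """One mock + one test construct, three wells each."""
    return build_layout(
        [("mock", Role.MOCK), ("A", Role.TEST_VARIANT)], plate_id="toy"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
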