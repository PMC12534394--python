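import numpy as np
import pytest

from neutrodent.membership import MembershipParams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def printed_params():
    """Membership parameters in the printed-form convention (bright = pathological)."""
    return MembershipParams(dark_lesions=False)


@pytest.fixture
def random_grid(rng):
    return rng.uniform(0.0, 1.0, size=(16, 16))
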