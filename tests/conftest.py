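import numpy as np
import pytest

import blastopower as bp


@pytest.fixture(scope="session")
def design8():
    """Reference balanced design: 8 blastocysts, 4 cells each, 32 samples."""
    return bp.build_balanced_design(8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
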