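import numpy as np
import pytest

import stainqc as sq


@pytest.fixture(scope="session")
def clean_stain():
    """One noise-free default stain with its ground truth (session-wide)."""
    params = sq.StainParams(seed=7, noise_sd=0.0)
    return sq.render_stain(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20210404)
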