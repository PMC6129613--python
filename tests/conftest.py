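import numpy as np
import pytest

import speechmf as smf


@pytest.fixture(scope="session")
def speech_context():
    """A speech-like [al] context at the default rate."""
    spec = smf.ContextSpec(kind="real_speech_like", precursor="al")
    return spec, smf.synthesize_context(spec)


@pytest.fixture(scope="session")
def cascade_07():
    """Binomial cascade, weight 0.7, 2**14 cells."""
    return smf.binomial_cascade(smf.CascadeSpec(p=0.7, levels=14, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
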