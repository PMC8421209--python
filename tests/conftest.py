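import pytest

from mmbti.simulate import make_random_reference


@pytest.fixture(scope="session")
def ref50k():
    """A 50 kb random reference shared by alignment/call unit tests."""
    return make_random_reference(50_000, gc=0.41, seed=7)


@pytest.fixture(scope="session")
def ref50k_seq(ref50k):
    return ref50k["sim1"]
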