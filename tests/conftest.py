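import pytest

from thermoflux.synth import make_fermentation_toy, make_linear_chain


@pytest.fixture
def toy():
    """The branched fermentation toy network (wild-type optimum Z = 8)."""
    return make_fermentation_toy()


@pytest.fixture
def chain():
    """Linear chain with closed-form optimum Z = uptake · yield."""
    return make_linear_chain(n=3, yield_coeff=0.5, uptake=10.0)
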