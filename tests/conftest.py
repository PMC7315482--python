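import pytest

from pcalib import MeanTestSpec


@pytest.fixture
def painkiller() -> MeanTestSpec:
    """The worked example: null mean 24 h, known variance 200, n = 50 patients.

    The sample-mean standard error is exactly 2, so z = (xbar - 24)/2.
    """
    return MeanTestSpec(mu0=24.0, sigma2=200.0, n=50)
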