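import pytest

from clonehistory.core import SampleMeta


@pytest.fixture
def meta70() -> SampleMeta:
    """Purity-0.70 near-diploid sample, the deeply characterized scenario."""
    return SampleMeta(purity=0.70, ploidy=2.0, sample_id="test", seed=0)
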