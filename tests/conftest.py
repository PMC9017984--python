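import pytest

from mdbias import PhysiologyParams, ProbeParams


@pytest.fixture(scope="session")
def phys():
    """Basal resting-muscle physiology."""
    return PhysiologyParams()


@pytest.fixture(scope="session")
def probe():
    """Default microdialysis probe (R0=0.5, f=3.33e-11 m3/s, Cp=2 mM)."""
    return ProbeParams()
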