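import numpy as np
import pytest

from ddscreen import AssayConfig, SampleTruth


@pytest.fixture
def cfg():
    """Default assay configuration (rain on, no false positives)."""
    return AssayConfig()


@pytest.fixture
def clean_cfg():
    """Noise-free cluster settings: no rain, no false positives."""
    return AssayConfig(rain_fraction=0.0, false_positive_rate=0.0)


@pytest.fixture
def typical_truth():
    """A normal newborn: 2 copies each of SMN1/SMN2, healthy TREC."""
    return SampleTruth(smn1_cn=2, smn2_cn=2, trec_blood=300.0, rpp30_blood=12_000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
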