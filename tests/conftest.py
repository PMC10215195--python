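import numpy as np
import pytest

from fosdecode import (
    GeneratorConfig,
    MontageConfig,
    StimulusProtocol,
    build_montage,
    generate_subject,
)

FS = 39.0625


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def default_montage():
    return build_montage(MontageConfig(), seed=0)


@pytest.fixture(scope="session")
def tiny_cohort(default_montage):
    """5 subjects x 1 revolution at an amplified planted effect: decodable
    quickly, shared by the slower pipeline-level tests."""
    proto = StimulusProtocol(n_revolutions=1)
    cfg = GeneratorConfig(protocol=proto, n_subjects=5, seed=0).scaled_effect(3.0)
    recs = [generate_subject(cfg, s, default_montage)[0] for s in range(5)]
    return cfg, proto, recs


def rng(seed=0):
    return np.random.default_rng(seed)
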