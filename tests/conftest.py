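import numpy as np
import pytest

from karyomie import build_space, constant_rates


@pytest.fixture
def single_chrom_space():
    """Dosage-sensitive single chromosome viable at 1..5 copies."""
    return build_space(1, [1], [5])


@pytest.fixture
def two_chrom_space():
    """Two critical chromosomes, each viable at 1..8 copies."""
    return build_space(2, [1, 1], [8, 8])


@pytest.fixture
def homogeneous_rates():
    return constant_rates(1.0, 0.4, 0.02)


@pytest.fixture
def rng():
    return np.random.default_rng(20230123)
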