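import numpy as np
import pytest

import cnvsig
from cnvsig import (
    CNV_GROUPS,
    NoiseConfig,
    SignatureConfig,
    adjust_confounds,
    make_atlas,
    make_signatures,
    simulate_clinical,
)


@pytest.fixture(scope="session")
def atlas100():
    return make_atlas(100, 7, seed=11)


@pytest.fixture(scope="session")
def atlas40():
    return make_atlas(40, 7, seed=12)


@pytest.fixture(scope="session")
def truth100(atlas100):
    return make_signatures(atlas100, seed=21)


@pytest.fixture(scope="session")
def clinical_small(truth100, atlas100):
    """One CNV group at n=50 against 150 controls (other groups minimal)."""
    sizes = {g: 4 for g in CNV_GROUPS}
    sizes["16p11.2del"] = 50
    sizes["control"] = 150
    return simulate_clinical(truth100, atlas100, sizes=sizes, seed=31)


@pytest.fixture(scope="session")
def adjusted_small(clinical_small):
    adj, _ = adjust_confounds(clinical_small.volumes, clinical_small.confounds)
    return adj
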