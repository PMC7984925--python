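import pytest

from qmnet import reference, run_reference_analysis
from qmnet.synthetic import StudyParams, generate_study


@pytest.fixture(scope="session")
def reference_compounds():
    return reference.compound_records()


@pytest.fixture(scope="session")
def reference_target_map():
    return reference.target_map()


@pytest.fixture(scope="session")
def reference_analysis():
    """Full offline reproduction run (fixed threshold 12, seed 0)."""
    return run_reference_analysis(seed=0)


@pytest.fixture(scope="session")
def synthetic_study():
    """Default-condition synthetic study, seed 1."""
    return generate_study(StudyParams(seed=1))


@pytest.fixture
def light_params():
    """Reduced fingerprint size for multi-seed sweeps (screening-independent
    properties only)."""
    def make(seed):
        return StudyParams(seed=seed, fingerprint_bits=128, decoys_per_compound=1)

    return make
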