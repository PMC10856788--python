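import numpy as np
import pytest

from dnasensor import (
    KNOWN_SENSORS,
    Landscape,
    NoiseModel,
    ResponseEnsemble,
    enumerate_k_mutants,
    validate_sequence,
)


@pytest.fixture(scope="session")
def original():
    return validate_sequence(KNOWN_SENSORS["original"], "original")


@pytest.fixture(scope="session")
def l114():
    return validate_sequence(KNOWN_SENSORS["L1-14"], "L1-14")


@pytest.fixture(scope="session")
def n21():
    return validate_sequence(KNOWN_SENSORS["N2-1"], "N2-1")


@pytest.fixture(scope="session")
def landscape():
    """Default additive landscape, calibrated to the published anchors."""
    return Landscape(seed=1)


@pytest.fixture(scope="session")
def zero_noise():
    return NoiseModel(relative_sd=0.0, replicate_count=3, seed=0)


@pytest.fixture(scope="session")
def full_library(original):
    """The complete 22,032-member exact-3 substitution library."""
    return enumerate_k_mutants(original, 3)


@pytest.fixture(scope="session")
def trained_ensemble(landscape, full_library):
    """Ensemble fit on 500 landscape-labelled library members (seeded sample)."""
    rng = np.random.default_rng(42)
    idx = rng.choice(len(full_library), size=700, replace=False)
    seqs = [full_library.members[i] for i in idx]
    labels = landscape.true_response_batch(seqs, "5HT")
    ens = ResponseEnsemble(random_state=0).fit(seqs[:500], labels[:500])
    return ens, seqs[500:], labels[500:]
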