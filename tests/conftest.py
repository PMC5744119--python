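import random

import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return random.Random(20170399)


@pytest.fixture
def random_peptide(rng):
    def make(length, alphabet=AA):
        return "".join(rng.choice(alphabet) for _ in range(length))

    return make


@pytest.fixture(scope="session")
def reference_fingerprint():
    from venomics.fingerprint import reference_fingerprint

    return reference_fingerprint()
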