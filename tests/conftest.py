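import numpy as np
import pytest
from hypothesis import settings

from hemospec.basis import synth_basis

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def basis():
    """Synthetic Gaussian-peak extinction basis on the 500-700 nm, 1 nm grid."""
    return synth_basis()


@pytest.fixture(scope="session")
def grid(basis):
    return basis.wavelengths_nm
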