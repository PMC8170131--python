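import numpy as np
import pytest

from motiffoot import synthetic_data as sd


@pytest.fixture(scope="session")
def aid_wm():
    """Planted WRC-style deaminase matrix used across tests."""
    return sd.aid_like_matrix()


@pytest.fixture(scope="session")
def eta_wm():
    """Planted WA-style polymerase matrix (A:T class)."""
    return sd.pol_eta_like_matrix()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_windows(rng, n, length=11, center=None):
    """Uniform ACGT windows, optionally with a fixed central base."""
    codes = rng.integers(0, 4, size=(n, length)).astype(np.uint8)
    if center is not None:
        codes[:, length // 2] = "ACGT".index(center)
    from motiffoot._seq import decode

    return [decode(row) for row in codes]
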