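import numpy as np
import pytest

from tmrconn import synthesize as syn


@pytest.fixture(scope="session")
def default_events():
    """One realisation of the default stimulation protocol."""
    return syn.generate_protocol(syn.ProtocolSpec(), rng_seed=7)


@pytest.fixture(scope="session")
def parcellation10():
    """115-parcel contiguous atlas on a 10x10x10 grid."""
    return syn.generate_parcellation((10, 10, 10), n_parcels=115, rng_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
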