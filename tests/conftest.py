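import logging

import numpy as np
import pytest

# Wilson stall warnings on estimated spectra are expected and checked
# explicitly where relevant; keep the test output readable.
logging.getLogger("specdag.factorization").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def unidir_var2():
    """Simulated 2-channel VAR(2) with unidirectional x->y coupling at 20 Hz,
    ~500 epochs, shared by the Granger-oracle tests."""
    from specdag.spectral import multitaper_csd, segment
    from specdag.synthetic import Edge, NetworkSpec, simulate_mvar

    spec = NetworkSpec(
        n_parcels=2,
        components_per_parcel=1,
        edges=[Edge(0, 1, 0.15, 20.0, 10.0)],
        fs=256.0,
        trial_length_s=60.0,
        n_trials=30,
        seed=42,
    )
    es = simulate_mvar(spec)
    epochs = segment(es, 4.0, 0.5)
    csd = multitaper_csd(epochs, 2.0)
    return spec, epochs, csd
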