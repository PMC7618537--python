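import pytest

import sorscreen as sc
from sorscreen import preprocessing, separation


@pytest.fixture(scope="session")
def grid():
    return sc.build_grid(200.0, 2000.0, 1.0)


@pytest.fixture(scope="session")
def noiseless_instrument():
    return sc.InstrumentModel(noise_scale=0.0)


@pytest.fixture(scope="session")
def genuine_content(grid):
    return sc.class_content(sc.CLASS_LIBRARY["genuine"], grid)


@pytest.fixture(scope="session")
def genuine_pair(genuine_content, noiseless_instrument, grid):
    """Noiseless genuine-vaccine SORS pair on the default grid."""
    return sc.simulate_pair(genuine_content, noiseless_instrument, grid, seed=0)


@pytest.fixture(scope="session")
def saline_study():
    """Genuine vs saline study: 10 vials × 6 replicates per class, default
    noise, separated and preprocessed with defaults (the screening setting)."""
    pairs = sc.generate_dataset(["genuine", "saline"], n_vials=10,
                                replicates=6, seed=1)
    sset, results = separation.separate_dataset(pairs)
    pre = preprocessing.preprocess_set(sset)
    return pairs, sset, results, pre


@pytest.fixture(scope="session")
def genuine_50(grid):
    """Fifty single-measurement genuine spectra, separated + preprocessed."""
    pairs = sc.generate_dataset(["genuine"], n_vials=50, replicates=1, seed=0)
    sset, _ = separation.separate_dataset(pairs)
    return preprocessing.preprocess_set(sset)
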