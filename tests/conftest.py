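import numpy as np
import pytest

import serosom


def small_config(seed: int = 7, **overrides) -> serosom.SimConfig:
    """Scaled-down default design: same seven conditions and structure,
    fewer genes, for fast unit tests."""
    kwargs = dict(
        n_genes=900,
        module_sizes={s: 60 for s in "ABDH"},
        n_go_terms=10,
        planted_term_size=40,
        go_term_size=(10, 40),
        seed=seed,
    )
    kwargs.update(overrides)
    return serosom.SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_sim():
    """(CountMatrix, SimTruth, SubtelomereMap, GODataset) at desk scale."""
    return serosom.simulate_dataset(small_config())


@pytest.fixture(scope="session")
def small_logtpm(small_sim):
    cm = small_sim[0]
    return serosom.log_transform(serosom.to_tpm(cm))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
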