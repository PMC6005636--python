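import numpy as np
import pytest

from dimerscope.synth import (
    EnsembleConfig,
    build_protomer_template,
    default_interaction_map,
    generate_daft_ensemble,
)

SEED = 11


@pytest.fixture(scope="session")
def template12():
    return build_protomer_template(seed=SEED)


@pytest.fixture(scope="session")
def imap_default():
    return default_interaction_map()


@pytest.fixture(scope="session")
def small_ensemble(template12, imap_default):
    """64 replicates, 1.5 us-equivalent: enough dimers for the analysis
    stages while keeping the suite fast."""
    cfg = EnsembleConfig(n_replicates=64, duration_us=1.5, seed=SEED)
    return generate_daft_ensemble(template12, imap_default, cfg)


@pytest.fixture(scope="session")
def tiny_ensemble(template12, imap_default):
    """8 replicates, short run, for file-IO and per-replicate tests."""
    cfg = EnsembleConfig(n_replicates=8, duration_us=0.3, seed=SEED)
    return generate_daft_ensemble(template12, imap_default, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
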