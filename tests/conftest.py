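import numpy as np
import pytest

import dmcmcp as d


@pytest.fixture(scope="session")
def stimuli8():
    return d.make_stimuli(8, 2, seed=42)


@pytest.fixture(scope="session")
def target8(stimuli8):
    return d.make_target_distribution(stimuli8, kind="unimodal", width=1.5)


@pytest.fixture(scope="session")
def graph8(stimuli8):
    S = d.pairwise_similarity(stimuli8)
    return d.bmatch_exact(S, 3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_session_log(stimuli8, target8, graph8):
    """A modest complete session (2 categories x 2 chains x 30 trials + extras)."""
    config = d.SessionConfig(
        categories=["a", "b"], chains_per_category=2, trials_per_chain=30,
        n_practice=4, n_catch=6, catch_pass_threshold=4, seed=7,
    )
    oracle = d.SimulatedChooser(target8, gamma=1.0, seed=11)
    pairs = d.make_catch_pairs(target8, config.n_catch, rng=3)
    return config, d.run_session(config, graph8, oracle, catch_pairs=pairs)
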