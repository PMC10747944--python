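import pytest

from semicorr import (
    MonteCarloConfig,
    generate,
    make_split,
    optimize,
    planted_demo_config,
)


@pytest.fixture(scope="session")
def planted_corpus():
    """2000-molecule noise-free corpus with planted promoter Br / suppressor n."""
    return generate(planted_demo_config(2000, seed=11))


@pytest.fixture(scope="session")
def planted_split(planted_corpus):
    return make_split(planted_corpus, seed=21, split_id=1)


@pytest.fixture(scope="session")
def trained_planted(planted_split):
    """One trained model + trace on the planted split (shared across tests)."""
    cfg = MonteCarloConfig(T=1, N=15, seed=31, target="tf1")
    model, trace = optimize(planted_split, cfg)
    return model, trace, cfg
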