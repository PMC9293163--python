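import pytest

from nichecast import (EnsembleConfig, EnsembleSDM, TrueNiche,
                       generate_climate_stack, sample_presences)


@pytest.fixture(scope="session")
def small_stack():
    """30x30 six-variable synthetic climate stack."""
    return generate_climate_stack(seed=11, n_rows=30, n_cols=30, smoothness=4.0)


@pytest.fixture(scope="session")
def truth():
    return TrueNiche(0.0, {"BIO3": 2.0, "BIO7": -1.5, "BIO10": 1.0})


@pytest.fixture(scope="session")
def presences(small_stack, truth):
    return sample_presences(small_stack, truth, 150, seed=12)


@pytest.fixture(scope="session")
def small_fit(small_stack, presences):
    """A quick ensemble fit shared by map-level tests (8 iterations)."""
    cfg = EnsembleConfig(n_iterations=8, learner_config={"rf_trees": 100})
    return EnsembleSDM(small_stack, presences, config=cfg).fit(seed=13)
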