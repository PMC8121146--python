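import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from harmonic_surprise.surprise import build_distribution
from harmonic_surprise.synth import SynthConfig, generate_corpus, make_fixture


@pytest.fixture(scope="session")
def toy6():
    return make_fixture("toy6")


@pytest.fixture(scope="session")
def toy6_baseline(toy6):
    """Baseline distribution of the toy corpus's first (year-2000) bin."""
    return build_distribution(toy6, ((2000, 1), (2000, 12)))


@pytest.fixture(scope="session")
def small_synth():
    """A small drifting corpus: 40 songs/year over 10 years."""
    return generate_corpus(
        SynthConfig(songs_per_year=40, n_years=10, seed=7)
    )
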