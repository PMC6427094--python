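import pytest

from mint.masker import MaskerConfig, make_masker_bed
from mint.melody import MelodyParams, generate_melody
from mint.trials import SessionConfig, build_session

MASTER_SEED = 20190314


@pytest.fixture(scope="session")
def session():
    """A full default task version (6 blocks x 20 trials + familiarization)."""
    return build_session(1, MASTER_SEED)


@pytest.fixture(scope="session")
def bed(session):
    """The masker bed referenced by the session fixture."""
    return make_masker_bed(session.seeds["bed_seed"], session.config.masker)


@pytest.fixture(scope="session")
def mini_config():
    """A trimmed configuration for tests that render audio to disk."""
    return SessionConfig(
        snr_levels=(0.0, -6.0),
        trials_per_block=4,
        familiarization_trials=2,
        masker=MaskerConfig(bed_seconds=12.0),
    )


@pytest.fixture(scope="session")
def mini_session(mini_config):
    return build_session(1, MASTER_SEED, mini_config)


@pytest.fixture
def melody():
    return generate_melody(MelodyParams(), seed=11)
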