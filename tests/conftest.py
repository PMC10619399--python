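import numpy as np
import pytest
from hypothesis import settings

from leida import (
    SynthConfig,
    generate_cohort,
    instantaneous_phase,
    preprocess_scan,
    split_arms,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A reduced paired cohort: 24 regions, 120 frames, 5 + 5 subjects."""
    return SynthConfig(
        n_regions=24,
        n_frames=120,
        n_states_true=3,
        n_recurrent=5,
        n_nonrecurrent=5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    scans, manifest, truth = generate_cohort(small_config)
    return scans, manifest, truth


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    scans, _, _ = small_cohort
    processed = [preprocess_scan(ts) for ts in scans]
    phases = {(ts.subject_id, ts.session): instantaneous_phase(ts) for ts in processed}
    return processed, phases


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
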