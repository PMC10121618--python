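import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from tribekit import EditSimConfig, simulate_edit_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Moderate simulated dataset shared across tests (seeded)."""
    return simulate_edit_dataset(EditSimConfig(n_genes=200, seed=11))


@pytest.fixture(scope="session")
def small_calls(small_dataset):
    from tribekit import call_edits, annotate_sites

    calls = call_edits(small_dataset.counts)
    return annotate_sites(calls, small_dataset.transcripts)
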